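"""Hydrogen/deuterium exchange kinetics.

The amide II / amide I area ratio, normalized to its t=0 value, tracks the
percentage of unexchanged amide protons. The decay is fitted as a sum of
first-order compartments plus a non-exchanging plateau,

    y(t) = plateau + sum_i a_i * exp(-ln2 * t / thalf_i),

with the plateau parameterized as 100 - sum(a_i) so amplitudes and plateau sum
to 100 exactly. Fitting is bounded least squares with a deterministic
multi-start grid over log-spaced half-lives (reproducible without a seed).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

AMIDE_II_WINDOW = (1525.0, 1565.0)
AMIDE_I_WINDOW = (1600.0, 1700.0)

_HALF_LIFE_GRID = (3.0, 10.0, 30.0, 120.0, 480.0)  # minutes


class HDXError(ValueError):
    pass


class HDXFitError(RuntimeError):
    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class HDXSeries:
    """Time series of amide II and amide I band areas."""

    times_min: np.ndarray
    amide_ii_area: np.ndarray
    amide_i_area: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        a2 = np.asarray(self.amide_ii_area, dtype=float)
        a1 = np.asarray(self.amide_i_area, dtype=float)
        if not (t.shape == a2.shape == a1.shape) or t.ndim != 1:
            raise HDXError("times and areas must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise HDXError("times must be strictly ascending")
        if np.any(a2 <= 0) or np.any(a1 <= 0):
            raise HDXError("band areas must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "amide_ii_area", a2)
        object.__setattr__(self, "amide_i_area", a1)


def read_series(path: str | Path) -> HDXSeries:
    """Read a TSV with columns time_min, amide_II_area, amide_I_area."""
    df = pd.read_csv(path, sep="\t")
    try:
        return HDXSeries(
            df["time_min"].to_numpy(),
            df["amide_II_area"].to_numpy(),
            df["amide_I_area"].to_numpy(),
        )
    except KeyError as exc:
        raise HDXError(f"{path}: missing column {exc}") from exc


def write_series(series: HDXSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_min": series.times_min,
            "amide_II_area": series.amide_ii_area,
            "amide_I_area": series.amide_i_area,
        }
    ).to_csv(path, sep="\t", index=False)


def percent_unexchanged(series: HDXSeries) -> tuple[np.ndarray, np.ndarray]:
    """(times, curve): amide II/I ratio normalized to 100% at t = 0."""
    if series.times_min[0] != 0:
        raise HDXError("series must include a t = 0 point")
    ratio = series.amide_ii_area / series.amide_i_area
    return series.times_min.copy(), 100.0 * ratio / ratio[0]


@dataclass(frozen=True)
class ExchangeFit:
    """Compartment decomposition of a %-unexchanged curve.

    Amplitudes and half-lives are reported sorted by ascending half-life;
    amplitudes + plateau sum to 100 by construction.
    """

    amplitudes: tuple[float, ...]
    half_lives_min: tuple[float, ...]
    plateau: float
    residual_norm: float
    n_starts: int = 0

    def __post_init__(self) -> None:
        if any(a < -1e-9 for a in self.amplitudes) or self.plateau < -1e-9:
            raise HDXError("amplitudes and plateau must be nonnegative")
        if any(t <= 0 for t in self.half_lives_min):
            raise HDXError("half-lives must be positive")
        total = sum(self.amplitudes) + self.plateau
        if abs(total - 100.0) > 0.5:
            raise HDXError(f"amplitudes + plateau = {total}, expected 100 +/- 0.5")

    def evaluate(self, times_min: np.ndarray) -> np.ndarray:
        t = np.asarray(times_min, dtype=float)
        y = np.full_like(t, self.plateau, dtype=float)
        for a, thalf in zip(self.amplitudes, self.half_lives_min):
            y = y + a * np.exp(-math.log(2.0) * t / thalf)
        return y


def _fit_model(params: np.ndarray, t: np.ndarray, n: int) -> np.ndarray:
    amps = params[:n]
    thalf = 10.0 ** params[n:]
    y = np.full_like(t, 100.0 - amps.sum(), dtype=float)
    for a, th in zip(amps, thalf):
        y = y + a * np.exp(-math.log(2.0) * t / th)
    return y


def fit_exchange(
    times_min: Sequence[float] | np.ndarray,
    curve: Sequence[float] | np.ndarray,
    n_components: int = 2,
) -> ExchangeFit:
    """Fit *n_components* first-order compartments plus a non-exchanging plateau.

    Multi-start over ordered half-life combinations from a fixed grid; the
    best-cost solution is returned. Raises :class:`HDXFitError` if no start
    converges.
    """
    if not 1 <= n_components <= 3:
        raise HDXError("n_components must be in 1..3")
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(curve, dtype=float)
    if t.size != y.size or t.ndim != 1:
        raise HDXError("times and curve must be 1-D arrays of equal length")
    if t.size < 2 * n_components + 2:
        raise HDXError(
            f"need at least {2 * n_components + 2} points for {n_components} components"
        )

    n = n_components
    exchanged = max(100.0 - float(y.min()), 0.0)
    # half-lives are capped at twice the observation span: beyond that a
    # compartment is indistinguishable from the plateau
    max_thalf = max(2.0 * float(t[-1] - t[0]), 1.0)
    lo = [0.0] * n + [math.log10(0.05)] * n
    hi = [100.0] * n + [math.log10(max_thalf)] * n

    def residuals(p):
        # soft barrier keeps sum(amplitudes) <= 100 (nonnegative plateau)
        penalty = 50.0 * max(p[:n].sum() - 100.0, 0.0)
        return np.append(_fit_model(p, t, n) - y, penalty)

    best = None
    failures = []
    starts = list(itertools.combinations(_HALF_LIFE_GRID, n))
    for combo in starts:
        a0 = [min(exchanged / n, 100.0 / n)] * n
        x0 = np.array(a0 + [math.log10(th) for th in combo])
        x0 = np.clip(x0, np.array(lo) + 1e-9, np.array(hi) - 1e-9)
        try:
            res = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf", max_nfev=2000,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(str(exc))
            continue
        if not res.success:
            failures.append(f"start {combo}: did not converge")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise HDXFitError(
            "exchange fit failed for every start",
            {"n_starts": len(starts), "failures": failures},
        )
    amps = best.x[:n]
    total = float(amps.sum())
    if total > 100.0:  # project the tiny residual barrier violation back
        amps = amps * (100.0 / total)
    thalf = 10.0 ** best.x[n:]
    order = np.argsort(thalf)
    plateau = max(100.0 - float(amps.sum()), 0.0)
    return ExchangeFit(
        amplitudes=tuple(float(a) for a in amps[order]),
        half_lives_min=tuple(float(th) for th in thalf[order]),
        plateau=plateau,
        residual_norm=float(np.linalg.norm(best.fun[:-1])),
        n_starts=len(starts),
    )


def unexchanged_helix_residues(
    plateau_pct: float,
    helix_fraction: float,
    n_residues: int,
) -> tuple[float, float]:
    """Unexchanged helical residues at long times.

    Returns (one_decimal, rounded): the value to one decimal place and per the
    reporting convention — one decimal below 10 residues, nearest integer
    otherwise.
    """
    from .ftir import helix_residue_count

    if not 0.0 <= plateau_pct <= 100.0:
        raise HDXError(f"plateau {plateau_pct} outside [0, 100] %")
    helix_residues = helix_residue_count(helix_fraction, n_residues)
    value = (plateau_pct / 100.0) * helix_residues
    one_decimal = round(value, 1)
    reported = one_decimal if value < 10.0 else float(round(value))
    return one_decimal, reported
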