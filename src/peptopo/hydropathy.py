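"""Sliding-window whole-residue octanol hydropathy with an engaged/disengaged salt-bridge option.

The bundled scale is the published whole-residue water->octanol transfer
free-energy set (kcal/mol, charged side-chain forms for D/E/K/R, neutral His).
A window total is the *negative* sum of the per-residue transfer energies over
the window, so favorable bilayer partitioning is positive. When an ion-lock
pair is marked engaged and both members fall inside a window, the two
individual charged-residue terms are replaced by a single small pair transfer
energy (``salt_bridge_pair_dg``, default +0.1 kcal/mol): an electrostatically
neutral ion pair costs far less to move into the membrane than two free
charges. A pair straddling the window edge is scored as disengaged for that
window (a bridge cannot be half-counted).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .peptides import STANDARD_AA, IonLockSpec, Peptide, PeptideError

DEFAULT_WINDOW = 19
DEFAULT_SALT_BRIDGE_PAIR_DG = 0.1


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue water->octanol transfer free energies, kcal/mol."""

    dg: Mapping[str, float]
    salt_bridge_pair_dg: float = DEFAULT_SALT_BRIDGE_PAIR_DG
    name: str = "ww-octanol"

    def __post_init__(self) -> None:
        missing = STANDARD_AA - set(self.dg)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues: {sorted(missing)}")
        for aa, value in self.dg.items():
            if value != value or value in (float("inf"), float("-inf")):
                raise ValueError(f"scale {self.name!r}: non-finite value for {aa}")
        pair_sum = self.dg["E"] + self.dg["K"]
        if not self.salt_bridge_pair_dg < pair_sum:
            raise ValueError(
                "salt_bridge_pair_dg must be below dG(E) + dG(K): "
                "engagement is never penalizing"
            )


def load_scale(path: str | Path | None = None,
               salt_bridge_pair_dg: float = DEFAULT_SALT_BRIDGE_PAIR_DG) -> HydropathyScale:
    """Load a scale from a two-column TSV (residue, dg_woct); default = bundled scale."""
    if path is None:
        text = resources.files("peptopo.data").joinpath("ww_octanol.tsv").read_text()
        name = "ww-octanol"
    else:
        text = Path(path).read_text()
        name = str(path)
    dg = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        dg[row["residue"].strip().upper()] = float(row["dg_woct"])
    return HydropathyScale(dg=dg, salt_bridge_pair_dg=salt_bridge_pair_dg, name=name)


@dataclass(frozen=True)
class HydropathyProfile:
    """Window totals (kcal/mol) indexed by 1-based window start."""

    peptide_id: str
    window_length: int
    totals: tuple[float, ...]  # totals[i] is the window starting at residue i+1

    @property
    def starts(self) -> range:
        return range(1, len(self.totals) + 1)

    def window_total(self, start: int) -> float:
        """Total for the window starting at 1-based residue *start*."""
        if not 1 <= start <= len(self.totals):
            raise PeptideError(f"no window starts at residue {start}")
        return self.totals[start - 1]

    @property
    def best_segment(self) -> tuple[int, int, float]:
        return best_transmembrane_segment(self)


def _engaged_pairs_in_window(locks: IonLockSpec | None, start: int, end: int):
    if locks is None or not locks.engaged:
        return []
    return [
        pair for pair in locks.pairs
        if start <= pair[0] <= end and start <= pair[1] <= end
    ]


def window_hydropathy(
    peptide: Peptide,
    scale: HydropathyScale | None = None,
    window: int = DEFAULT_WINDOW,
    locks: IonLockSpec | None = None,
) -> HydropathyProfile:
    """Compute sliding-window hydropathy totals (kcal/mol, higher = more membrane-favorable)."""
    if scale is None:
        scale = load_scale()
    n = len(peptide)
    if window < 1 or window > n:
        raise PeptideError(
            f"window {window} invalid for {peptide.id!r} (length {n})"
        )
    if locks is not None:
        locks.validate_for(peptide)
        for anion, cation in locks.pairs:
            if peptide.residue(anion) != "E" or peptide.residue(cation) != "K":
                raise PeptideError(
                    f"ion-lock pair ({anion}, {cation}) does not sit on E/K residues "
                    f"of {peptide.id!r}"
                )
    dg = scale.dg
    totals = []
    for start in range(1, n - window + 2):
        end = start + window - 1
        total_dg = sum(dg[peptide.residue(i)] for i in range(start, end + 1))
        for anion, cation in _engaged_pairs_in_window(locks, start, end):
            total_dg += scale.salt_bridge_pair_dg - dg["E"] - dg["K"]
        totals.append(-total_dg)
    return HydropathyProfile(peptide.id, window, tuple(totals))


def best_transmembrane_segment(profile: HydropathyProfile) -> tuple[int, int, float]:
    """Window with the maximal total; ties broken by the smallest start. 1-based inclusive."""
    if not profile.totals:
        raise PeptideError("empty hydropathy profile")
    best_idx = max(range(len(profile.totals)), key=lambda i: (profile.totals[i], -i))
    start = best_idx + 1
    return (start, start + profile.window_length - 1, profile.totals[best_idx])


def engagement_delta(
    peptide: Peptide,
    scale: HydropathyScale | None = None,
    window: int = DEFAULT_WINDOW,
    locks: IonLockSpec | None = None,
) -> float:
    """Best-segment total with the bridge(s) engaged minus with them disengaged (>= 0)."""
    if locks is None:
        raise PeptideError("engagement_delta requires a non-empty ion-lock spec")
    engaged = IonLockSpec(locks.pairs, engaged=True)
    disengaged = IonLockSpec(locks.pairs, engaged=False)
    best_on = best_transmembrane_segment(window_hydropathy(peptide, scale, window, engaged))
    best_off = best_transmembrane_segment(window_hydropathy(peptide, scale, window, disengaged))
    return best_on[2] - best_off[2]
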