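"""Polarized-ATR analysis: dichroic ratio -> order parameters -> maximum helix tilt.

Thick-film evanescent-wave model. The inversion chain is

    R = A_par / A_perp
    S_dipole = (Ex^2 - R*Ey^2 + Ez^2) / (Ex^2 - R*Ey^2 - 2*Ez^2)
    S_helix  = S_dipole / [(3 cos^2(alpha) - 1) / 2]
    theta    = arccos( sqrt((2*S_helix + 1) / 3) )

with alpha the transition-dipole angle to the helix axis. The isotropic limit
reproduces R = (Ex^2 + Ez^2) / Ey^2 (about 2.00 for the default fields).
Because multilayer films are never perfectly ordered, the derived angle is a
*maximum* tilt from the membrane normal. Degrees at the interface, radians
internally.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

from .ftir import Spectrum

HELIX_BAND_WINDOW = (1645.0, 1662.0)


class OrientationError(ValueError):
    pass


class OutOfModelRangeError(OrientationError):
    """R falls outside the range the field parameters can produce.

    Re-run with ``clamp=True`` to map out-of-range ratios to 0 deg / 90 deg.
    """


@dataclass(frozen=True)
class FieldParams:
    """Evanescent-field amplitudes and the transition-dipole angle (degrees)."""

    e_x: float = 1.398
    e_y: float = 1.516
    e_z: float = 1.625
    alpha_deg: float = 39.0

    def __post_init__(self) -> None:
        if abs(self.s_alpha) < 1e-12:
            raise OrientationError("alpha at the magic angle: dipole order parameter undefined")

    @property
    def s_alpha(self) -> float:
        c = math.cos(math.radians(self.alpha_deg))
        return (3.0 * c * c - 1.0) / 2.0

    @property
    def r_isotropic(self) -> float:
        return (self.e_x**2 + self.e_z**2) / self.e_y**2

    @property
    def r_range(self) -> tuple[float, float]:
        """(R_min, R_max): attainable dichroic ratios for S_helix in [-0.5, 1]."""
        r0 = forward_dichroic_ratio(0.0, self)
        r90 = forward_dichroic_ratio(90.0, self)
        return (min(r0, r90), max(r0, r90))


DEFAULT_FIELDS = FieldParams()


@dataclass(frozen=True)
class PolarizedPair:
    """Amide-I band areas at 0 deg (parallel) and 90 deg (perpendicular) polarization.

    Either pass the integrated areas directly, or the two full spectra (areas
    are then integrated by trapezoid over *band_window* at call time).
    """

    a_parallel: Optional[float] = None
    a_perpendicular: Optional[float] = None
    spectrum_parallel: Optional[Spectrum] = None
    spectrum_perpendicular: Optional[Spectrum] = None

    def areas(self, band_window: tuple[float, float] = HELIX_BAND_WINDOW) -> tuple[float, float]:
        if self.a_parallel is not None and self.a_perpendicular is not None:
            par, perp = self.a_parallel, self.a_perpendicular
        elif self.spectrum_parallel is not None and self.spectrum_perpendicular is not None:
            par = self.spectrum_parallel.integrate(*band_window)
            perp = self.spectrum_perpendicular.integrate(*band_window)
        else:
            raise OrientationError("PolarizedPair needs two areas or two spectra")
        if par <= 0 or perp <= 0:
            raise OrientationError(f"band areas must be positive (got {par}, {perp})")
        return par, perp


@dataclass(frozen=True)
class OrientationResult:
    dichroic_ratio: float
    s_dipole: float
    s_helix: float
    theta_max_deg: float


def dichroic_ratio(
    pair: PolarizedPair,
    band_window: tuple[float, float] = HELIX_BAND_WINDOW,
) -> float:
    """R = A_parallel / A_perpendicular over the helix amide-I band."""
    par, perp = pair.areas(band_window)
    return par / perp


def order_parameter(
    r: float,
    fields: FieldParams = DEFAULT_FIELDS,
    clamp: bool = False,
) -> tuple[float, float]:
    """(S_dipole, S_helix) from a dichroic ratio.

    Raises :class:`OutOfModelRangeError` when *r* is outside the attainable
    range unless ``clamp=True``, which pins S_helix to 1 (R too high) or -0.5
    (R too low) with a warning.
    """
    r_min, r_max = fields.r_range
    tol = 1e-9
    if not (r_min - tol <= r <= r_max + tol):
        if not clamp:
            raise OutOfModelRangeError(
                f"R={r:.4g} outside attainable range [{r_min:.4g}, {r_max:.4g}] "
                "for these field parameters; pass clamp=True to pin to 0/90 degrees"
            )
        warnings.warn(
            f"R={r:.4g} outside [{r_min:.4g}, {r_max:.4g}]; clamping", stacklevel=2
        )
        s_helix = 1.0 if r > r_max else -0.5
        return (s_helix * fields.s_alpha, s_helix)
    num = fields.e_x**2 - r * fields.e_y**2 + fields.e_z**2
    den = fields.e_x**2 - r * fields.e_y**2 - 2.0 * fields.e_z**2
    s_dipole = num / den
    s_helix = s_dipole / fields.s_alpha
    s_helix = min(max(s_helix, -0.5), 1.0)  # guard round-off at the range edges
    return (s_dipole, s_helix)


def tilt_angle(s_helix: float) -> float:
    """Maximum tilt (degrees from the membrane normal) from the helix order parameter."""
    if not -0.5 - 1e-12 <= s_helix <= 1.0 + 1e-12:
        raise OrientationError(f"S_helix={s_helix} outside [-0.5, 1]")
    c2 = (2.0 * min(max(s_helix, -0.5), 1.0) + 1.0) / 3.0
    return math.degrees(math.acos(math.sqrt(c2)))


def helix_order_parameter(theta_deg: float) -> float:
    """S = (3 cos^2(theta) - 1) / 2."""
    c = math.cos(math.radians(theta_deg))
    return (3.0 * c * c - 1.0) / 2.0


def forward_dichroic_ratio(theta_deg: float, fields: FieldParams = DEFAULT_FIELDS) -> float:
    """Forward model: dichroic ratio expected for a helix tilted *theta_deg*.

    Used as the generator/oracle for the inverse chain.
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise OrientationError(f"theta={theta_deg} outside [0, 90] degrees")
    s_dipole = helix_order_parameter(theta_deg) * fields.s_alpha
    k_z = (2.0 * s_dipole + 1.0) / 3.0
    num = fields.e_x**2 * (1.0 - k_z) / 2.0 + fields.e_z**2 * k_z
    den = fields.e_y**2 * (1.0 - k_z) / 2.0
    return num / den


def analyze_pair(
    pair: PolarizedPair,
    band_window: tuple[float, float] = HELIX_BAND_WINDOW,
    fields: FieldParams = DEFAULT_FIELDS,
    clamp: bool = False,
) -> OrientationResult:
    """Full chain: areas -> R -> (S_dipole, S_helix) -> maximum tilt angle."""
    r = dichroic_ratio(pair, band_window)
    s_dipole, s_helix = order_parameter(r, fields, clamp=clamp)
    return OrientationResult(r, s_dipole, s_helix, tilt_angle(s_helix))
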