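"""Poly-T angle modules: map binding angles to top/bottom spacer lengths.

Each bonded face carries two rows of four ssDNA strands.  The poly-T
spacer lengths of the top row (l_top) and bottom row (l_bottom) set the
preferred binding angle: equal lengths give a planar 0° bond, l_top >
l_bottom a positive (outward-convex) angle, l_top < l_bottom a negative
one.  The quantitative mapping is a calibrated two-row lever model

    θ = 2·arctan( λ·(l_top − l_bottom) / (2·d) )

with d the distance between the strand rows on the face and λ the
effective extension per poly-T nucleotide.  The default calibration pins
the demonstrated anchor (l_top, l_bottom) = (14, 3) to θ = 41.8°, with
d = 10 nm (rows four helices apart on the 15 nm face), giving
λ ≈ 0.694 nm/nt — within the plausible ssDNA range of 0.3–0.8 nm/nt.

Sticky-end (bond module) lengths follow the empirical on/off-rate rules:
5 bp for bottom rows, 5 bp for top rows with l_top < 10, 6 bp for
l_top = 10–14, and 7 bp when stronger (hierarchical) binding is wanted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "AngleModule",
    "GeometryCalibration",
    "StickyLengths",
    "DEFAULT_CALIBRATION",
    "lengths_to_angle",
    "angle_to_lengths",
    "sticky_length_for",
]

POLY_T_MAX = 20
DEMONSTRATED_RANGE = (3, 14)


class ExtrapolationWarning(UserWarning):
    """Poly-T length outside the demonstrated 3-14 nt range."""


class InfeasibleAngleError(ValueError):
    """Requested angle needs a poly-T length outside [0, 20] nt."""


@dataclass(frozen=True)
class AngleModule:
    """Top/bottom poly-T spacer lengths (nt) of one face's angle module."""

    l_top: int
    l_bottom: int
    passivated: bool = False

    def __post_init__(self) -> None:
        if self.passivated:
            return
        for name, l in (("l_top", self.l_top), ("l_bottom", self.l_bottom)):
            if not 0 <= l <= POLY_T_MAX:
                raise ValueError(f"{name}={l} outside [0, {POLY_T_MAX}] nt")


@dataclass(frozen=True)
class GeometryCalibration:
    """Face geometry: row separation d (nm) and per-nt extension λ (nm/nt)."""

    row_separation_d: float = 10.0
    nt_length_lambda: float = 2.0 * 10.0 * math.tan(math.radians(41.8 / 2.0)) / 11.0

    def __post_init__(self) -> None:
        if self.row_separation_d <= 0:
            raise ValueError("row separation d must be positive")
        if not 0.3 <= self.nt_length_lambda <= 0.8:
            raise ValueError(
                f"nt extension lambda={self.nt_length_lambda:.3f} outside [0.3, 0.8] nm"
            )


#: Anchored so that (l_top, l_bottom) = (14, 3) maps to exactly 41.8 degrees.
DEFAULT_CALIBRATION = GeometryCalibration()


class StickyLengths(NamedTuple):
    """Sticky-end lengths (bp) for the top and bottom strand rows."""

    top: int
    bottom: int


def lengths_to_angle(
    mod: AngleModule, cal: GeometryCalibration = DEFAULT_CALIBRATION
) -> float:
    """Preferred binding angle (signed degrees) of an angle module."""
    if mod.passivated:
        raise ValueError("passivated face carries no angle module")
    delta = mod.l_top - mod.l_bottom
    return 2.0 * math.degrees(
        math.atan(cal.nt_length_lambda * delta / (2.0 * cal.row_separation_d))
    )


def angle_to_lengths(
    theta: float, cal: GeometryCalibration = DEFAULT_CALIBRATION
) -> AngleModule:
    """Angle module targeting ``theta`` (degrees), fixed-side convention.

    The shorter row is pinned at 3 poly-T (l_bottom for positive angles,
    l_top for negative ones) and the other row varies; the varying length is
    rounded to the nearest integer nucleotide, so a round trip through
    :func:`lengths_to_angle` is exact only up to one-nt quantization.
    """
    if not abs(theta) < 90.0:
        raise InfeasibleAngleError(f"|theta|={abs(theta)} >= 90 degrees")
    fixed = 3
    delta = (
        2.0
        * cal.row_separation_d
        * math.tan(math.radians(theta) / 2.0)
        / cal.nt_length_lambda
    )
    varying = fixed + round(abs(delta))
    if varying > POLY_T_MAX:
        raise InfeasibleAngleError(
            f"theta={theta} deg needs a {varying}-nt poly-T (> {POLY_T_MAX})"
        )
    if theta >= 0:
        mod = AngleModule(l_top=varying, l_bottom=fixed)
    else:
        mod = AngleModule(l_top=fixed, l_bottom=varying)
    _warn_if_extrapolated(mod)
    return mod


def _warn_if_extrapolated(mod: AngleModule) -> None:
    lo, hi = DEMONSTRATED_RANGE
    for l in (mod.l_top, mod.l_bottom):
        if not lo <= l <= hi:
            warnings.warn(
                f"poly-T length {l} outside demonstrated range {lo}-{hi} nt",
                ExtrapolationWarning,
                stacklevel=3,
            )
            return


def sticky_length_for(mod: AngleModule, hierarchical: bool = False) -> StickyLengths:
    """Sticky-end lengths (bp) for each strand row of an angle module.

    Longer top spacers pay a larger entropic cost to present their sticky
    end, so they get an extra base pair; hierarchical bonds (meant to bind
    earlier/stronger than the rest) get 7 bp on both rows.
    """
    if mod.passivated:
        raise ValueError("passivated face carries no bond module")
    if hierarchical:
        return StickyLengths(top=7, bottom=7)
    if mod.l_top > 14:
        warnings.warn(
            f"l_top={mod.l_top} > 14 nt not demonstrated; extrapolating to 7 bp",
            ExtrapolationWarning,
            stacklevel=2,
        )
        return StickyLengths(top=7, bottom=5)
    top = 6 if mod.l_top >= 10 else 5
    return StickyLengths(top=top, bottom=5)
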