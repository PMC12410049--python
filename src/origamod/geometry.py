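"""Closed-form geometry linking target assemblies to required binding angles.

Triangular subunits tile surfaces; the signed binding angle θ between two
bonded subunits sets the local curvature.  A subunit beveled by α on a bond
edge produces θ = 2α.  Closed icosahedral shells follow Caspar–Klug theory:
a shell of triangulation number T = h² + hk + k² contains 20·T triangular
subunits, with 5-fold vertices requiring θ = 41.8° and the remaining
(quasi-6-fold) bonds planar.  Achiral tubes (m, 0) close m subunits around
the circumference.

Sign convention: positive θ bends the subunit tops (outer surface) toward
each other, giving an outward-convex shell; 0 is planar.  Angles are kept at
full precision internally and rounded only for presentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "StructureKind",
    "TargetStructure",
    "BindingAngleSpec",
    "bevel_to_binding",
    "vertex_binding_angle",
    "ck_T_number",
    "shell_subunit_count",
    "shell_angle_requirements",
    "tube_angle_requirements",
    "is_ck_number",
]


class StructureKind(str, Enum):
    CONTINUOUS_TILING = "continuous_tiling"
    TETRAMER_TILING = "tetramer_tiling"
    SHELL = "shell"
    TUBE = "tube"
    VERTEX = "vertex"


class UnsupportedTargetError(ValueError):
    """Raised for targets that are geometrically valid but not demonstrated."""


@dataclass(frozen=True)
class TargetStructure:
    """Declarative description of the goal assembly.

    Exactly the fields of the active ``kind`` are set: ``T`` (or ``h, k``)
    for shells, ``m`` for tubes, ``n_fold`` for vertex subassemblies.
    """

    kind: StructureKind
    T: Optional[int] = None
    h: Optional[int] = None
    k: Optional[int] = None
    m: Optional[int] = None
    n_fold: Optional[int] = None

    def __post_init__(self) -> None:
        kind = StructureKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is StructureKind.SHELL:
            if self.T is None:
                if self.h is None or self.k is None:
                    raise ValueError("shell requires T or (h, k)")
                object.__setattr__(self, "T", ck_T_number(self.h, self.k))
            elif self.h is not None and self.k is not None:
                if ck_T_number(self.h, self.k) != self.T:
                    raise ValueError(
                        f"T={self.T} inconsistent with (h,k)=({self.h},{self.k})"
                    )
            if not is_ck_number(self.T):
                raise ValueError(f"T={self.T} is not a Caspar-Klug number")
            if self.m is not None or self.n_fold is not None:
                raise ValueError("shell target carries only T/(h,k)")
        elif kind is StructureKind.TUBE:
            if self.m is None:
                raise ValueError("tube requires lattice number m")
            if self.m < 4:
                raise ValueError(f"tube lattice number m={self.m} < 4")
            if any(v is not None for v in (self.T, self.h, self.k, self.n_fold)):
                raise ValueError("tube target carries only m")
        elif kind is StructureKind.VERTEX:
            if self.n_fold is None:
                raise ValueError("vertex requires n_fold")
            if not 3 <= self.n_fold <= 6:
                raise ValueError(f"n_fold={self.n_fold} outside [3, 6]")
            if any(v is not None for v in (self.T, self.h, self.k, self.m)):
                raise ValueError("vertex target carries only n_fold")
        else:  # tilings
            if any(
                v is not None for v in (self.T, self.h, self.k, self.m, self.n_fold)
            ):
                raise ValueError(f"{kind.value} target carries no extra fields")


@dataclass(frozen=True)
class BindingAngleSpec:
    """A bond class and its target binding angle.

    ``theta_target`` is signed degrees, positive convex toward the outside.
    The magnitude is bounded by 90° (closed at the bound: the m=4 tube edge
    case sits exactly at 90°); planar bonds have theta_target = 0.
    """

    bond_class: str
    theta_target: float
    count_per_structure: int = 0

    def __post_init__(self) -> None:
        if not -90.0 <= self.theta_target <= 90.0:
            raise ValueError(
                f"theta_target={self.theta_target} outside [-90, 90] degrees"
            )


def bevel_to_binding(alpha: float) -> float:
    """Binding angle θ = 2α for a subunit with bevel angle α (degrees)."""
    if not 0.0 <= alpha < 90.0:
        raise ValueError(f"bevel angle alpha={alpha} outside [0, 90)")
    return 2.0 * alpha


def vertex_binding_angle(n_fold: int) -> float:
    """Binding angle (degrees) at which n equilateral triangles close a vertex.

    For n = 6 the six 60° face angles sum to 2π and the vertex is exactly
    planar (0°).  For n in {3, 4, 5} the triangles fold into the vertex of
    the deltahedral solid with n-fold vertices (tetrahedron, octahedron,
    icosahedron) whose dihedral δ satisfies sin(δ/2) = cos(π/n)/sin(π/3);
    the binding angle is the dihedral complement 180° − δ.
    """
    if not isinstance(n_fold, int) or not 3 <= n_fold <= 6:
        raise ValueError(f"n_fold={n_fold}: no convex closure outside [3, 6]")
    if n_fold == 6:
        return 0.0
    half = math.asin(math.cos(math.pi / n_fold) / math.sin(math.pi / 3.0))
    dihedral = 2.0 * math.degrees(half)
    return 180.0 - dihedral


def ck_T_number(h: int, k: int) -> int:
    """Caspar-Klug triangulation number T = h² + hk + k²."""
    if h < 0 or k < 0:
        raise ValueError("h and k must be non-negative")
    if h + k == 0:
        raise ValueError("h and k cannot both be zero")
    return h * h + h * k + k * k


def is_ck_number(T: Optional[int]) -> bool:
    """True if T is a valid triangulation number for some (h, k)."""
    if T is None or T < 1:
        return False
    for h in range(int(math.isqrt(T)) + 1):
        for k in range(int(math.isqrt(T)) + 1):
            if h + k > 0 and h * h + h * k + k * k == T:
                return True
    return False


def shell_subunit_count(T: int) -> int:
    """Number of triangular subunits in a closed T-shell: 20·T."""
    if not is_ck_number(T):
        raise ValueError(f"T={T} is not a Caspar-Klug triangulation number")
    return 20 * T


def shell_angle_requirements(T: int) -> list[BindingAngleSpec]:
    """Bond classes and target angles for the demonstrated icosahedral shells.

    T=1: a single bond class at 41.8° (every edge sits between 5-fold
    vertices).  T=4: a planar 0° class inside each flat tetramer and the
    41.8° class along the 5-fold (inter-tetramer) bonds.  Other T values are
    rejected: their quasi-equivalent bond enumeration is not demonstrated.
    """
    if not is_ck_number(T):
        raise ValueError(f"T={T} is not a Caspar-Klug triangulation number")
    theta5 = vertex_binding_angle(5)
    if T == 1:
        return [BindingAngleSpec("5-fold", theta5, count_per_structure=30)]
    if T == 4:
        # 20 flat tetramers: 3 internal (3-fold) bonds each; 30 5-fold edges
        # between tetramers, doubled because each T=4 edge carries two bonds.
        return [
            BindingAngleSpec("3-fold", 0.0, count_per_structure=60),
            BindingAngleSpec("5-fold", theta5, count_per_structure=60),
        ]
    raise UnsupportedTargetError(
        f"T={T} shell not demonstrated in source; supported: T in {{1, 4}}"
    )


def tube_angle_requirements(
    m: int,
    theta_circumferential: Optional[float] = None,
    theta_axial: Optional[float] = None,
) -> list[BindingAngleSpec]:
    """Bond classes for an achiral (m, 0) tube.

    The circumferential angle defaults to the 360°/m turning model: the m
    subunits of the shortest self-closing loop turn through a total of 360°.
    This is approximate (no exact closure formula is adopted) and can be
    overridden with ``theta_circumferential``.  The axial class carries the
    negative angle of the demonstrated recipe (l_top=3 < l_bottom=8),
    computed from the default length-to-angle calibration unless overridden.
    """
    if m < 4:
        raise ValueError(f"tube lattice number m={m} < 4")
    if theta_circumferential is None:
        theta_circumferential = 360.0 / m
    if theta_axial is None:
        from .anglemod import AngleModule, lengths_to_angle

        theta_axial = lengths_to_angle(AngleModule(l_top=3, l_bottom=8))
    return [
        BindingAngleSpec(
            "circumferential", theta_circumferential, count_per_structure=2 * m
        ),
        BindingAngleSpec("axial", theta_axial, count_per_structure=m),
    ]
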