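"""Synthetic ensembles with the statistical structure the analysis assumes.

The generators emulate the measured dimer ensembles (cryo-EM multibody
poses, coarse-grained trajectory face coordinates, gel densitometry
lanes) as i.i.d. Gaussian fluctuations about a mean joint geometry:
bend about the hinge, twist about the bond axis and stretch along it,
sampled independently.  Real data have correlated modes, non-Gaussian
tails, misfolded particles and imaging noise, none of which is modelled;
round-tripping these fixtures through the analysis therefore validates
the estimators, not the experiments.

All generators are reproducible: a fixed seed yields byte-identical
tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .joints import (
    REFERENCE_T0,
    AngleEnsemble,
    EnsembleSource,
    PosePair,
    sigma_from_modulus,
)

__all__ = [
    "EnsembleRecipe",
    "DEFAULT_FACE_TEMPLATE",
    "default_face_template",
    "sample_angle_ensemble",
    "sample_poses",
    "posed_face_coordinates",
    "PosedFaces",
    "synthetic_gel_profile",
]

#: Face cross-section of the subunit core: 15 nm wide, strand rows 10 nm apart.
FACE_WIDTH_NM = 15.0
ROW_SEPARATION_NM = 10.0
BOND_GAP_NM = 2.0


@dataclass(frozen=True)
class EnsembleRecipe:
    """Parameters of a synthetic dimer ensemble.

    Exactly one of ``sigma`` (degrees) or ``modulus`` (k_B·T₀/rad²) is
    given; a modulus is converted to the equipartition spread at
    ``temperature``.  ``twist_sigma`` (degrees) and ``stretch_sigma`` (nm)
    default to the minor-mode regime (small compared to bend).
    """

    mean_angle: float
    sigma: Optional[float] = None
    modulus: Optional[float] = None
    twist_sigma: float = 0.0
    stretch_sigma: float = 0.0
    n: int = 1000
    seed: int = 0
    temperature: float = REFERENCE_T0

    def __post_init__(self) -> None:
        if (self.sigma is None) == (self.modulus is None):
            raise ValueError("give exactly one of sigma or modulus")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")

    @property
    def bend_sigma(self) -> float:
        if self.sigma is not None:
            return self.sigma
        return sigma_from_modulus(self.modulus, self.temperature)


def default_face_template() -> np.ndarray:
    """8 anchor points of one face: two rows of 4 spanning the face.

    Width 15 nm (x), bottom row at y = 0 and top row at y = 10 nm, in the
    face plane z = 0, matching the core's rectangular cross-section.
    """
    xs = np.linspace(-FACE_WIDTH_NM / 2.0, FACE_WIDTH_NM / 2.0, 4)
    pts = [(x, y, 0.0) for y in (0.0, ROW_SEPARATION_NM) for x in xs]
    return np.array(pts, dtype=float)


DEFAULT_FACE_TEMPLATE = default_face_template()


def sample_angle_ensemble(recipe: EnsembleRecipe) -> AngleEnsemble:
    """I.i.d. Gaussian bend angles at the recipe's mean and spread."""
    rng = np.random.default_rng(recipe.seed)
    angles = rng.normal(recipe.mean_angle, recipe.bend_sigma, size=recipe.n)
    return AngleEnsemble(
        angles, temperature=recipe.temperature, source=EnsembleSource.SYNTHETIC
    )


def sample_poses(recipe: EnsembleRecipe) -> tuple[list[PosePair], np.ndarray]:
    """Sample relative poses (bend/twist/stretch) and the drawn bend angles.

    Bend is a rotation about the hinge axis x, twist about the bond axis
    z, stretch a translation along z; the three are drawn independently.
    Returns the pose list and the bend angles (degrees).
    """
    rng = np.random.default_rng(recipe.seed)
    bend = rng.normal(recipe.mean_angle, recipe.bend_sigma, size=recipe.n)
    twist = rng.normal(0.0, recipe.twist_sigma, size=recipe.n)
    stretch = rng.normal(0.0, recipe.stretch_sigma, size=recipe.n)
    poses = [
        PosePair(
            rotvec=(math.radians(b), 0.0, math.radians(t)),
            translation=(0.0, 0.0, s),
        )
        for b, t, s in zip(bend, twist, stretch)
    ]
    return poses, bend


@dataclass
class PosedFaces:
    """Posed dimer face coordinates and the generating bend angles."""

    frames: list[tuple[np.ndarray, np.ndarray]]  # (points_a, points_b) per sample
    bend_angles: np.ndarray  # degrees, as sampled
    ref_vector: np.ndarray  # positive hinge direction for sign convention
    recipe: EnsembleRecipe

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for s, (pa, pb) in enumerate(self.frames):
            for body, pts in (("A", pa), ("B", pb)):
                for pid, (x, y, z) in enumerate(pts):
                    rows.append(
                        {
                            "sample": s,
                            "body": body,
                            "point_id": pid,
                            "x": x,
                            "y": y,
                            "z": z,
                        }
                    )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9f")


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)


def posed_face_coordinates(
    recipe: EnsembleRecipe,
    face_template: Optional[np.ndarray] = None,
) -> PosedFaces:
    """Pose two face point sets at sampled bend/twist/stretch fluctuations.

    Face A sits in the z = 0 plane; face B starts parallel at z = 2 nm
    (the bond gap) and is twisted about the bond axis through the face
    center, then bent about the hinge (the bottom edge, along x, at the
    bond midplane), then stretched along the bond axis.  The bend angle
    recovered by :func:`origamod.joints.dimer_angle_from_faces` with
    ``ref_vector = +x`` equals the sampled bend exactly at zero noise.
    """
    template = DEFAULT_FACE_TEMPLATE if face_template is None else np.asarray(face_template, float)
    if template.ndim != 2 or template.shape[1] != 3 or template.shape[0] < 3:
        raise ValueError("face template needs >= 3 points of dimension 3")
    spans = template.max(axis=0) - template.min(axis=0)
    if np.sort(spans)[-2] <= 0:
        raise ValueError("degenerate face template (collinear points)")
    rng = np.random.default_rng(recipe.seed)
    bend = rng.normal(recipe.mean_angle, recipe.bend_sigma, size=recipe.n)
    twist = rng.normal(0.0, recipe.twist_sigma, size=recipe.n)
    stretch = rng.normal(0.0, recipe.stretch_sigma, size=recipe.n)

    center_b = np.array([0.0, ROW_SEPARATION_NM / 2.0, BOND_GAP_NM])
    hinge_point = np.array([0.0, 0.0, BOND_GAP_NM / 2.0])
    frames = []
    for b, t, s in zip(bend, twist, stretch):
        pts_b = template + np.array([0.0, 0.0, BOND_GAP_NM])
        pts_b = (pts_b - center_b) @ _rot_z(t).T + center_b
        # bend: rotate B about the hinge so that for b > 0 the tops approach
        pts_b = (pts_b - hinge_point) @ _rot_x(-b).T + hinge_point
        pts_b = pts_b + np.array([0.0, 0.0, s])
        frames.append((template.copy(), pts_b))
    return PosedFaces(
        frames=frames,
        bend_angles=bend,
        ref_vector=np.array([1.0, 0.0, 0.0]),
        recipe=recipe,
    )


def synthetic_gel_profile(
    target_fraction: float,
    peak_position: float = 30.0,
    peak_width: float = 2.0,
    smear_center: float = 65.0,
    smear_width: float = 8.0,
    noise_sigma: float = 0.0,
    baseline: float = 0.05,
    seed: int = 0,
    n_points: int = 1001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A gel lane whose target-peak area fraction is exact before noise.

    The lane is a narrow Gaussian target band carrying ``target_fraction``
    of the signal area plus a broad smear carrying the rest, on a constant
    baseline; the background table holds the baseline (an empty lane).
    Returns (profile, background) tables with columns distance, intensity.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must be in [0, 1]")
    x = np.linspace(0.0, 100.0, n_points)

    def gauss(mu, sig):
        return np.exp(-0.5 * ((x - mu) / sig) ** 2) / (sig * math.sqrt(2 * math.pi))

    signal = target_fraction * gauss(peak_position, peak_width)
    signal = signal + (1.0 - target_fraction) * gauss(smear_center, smear_width)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sigma, size=x.size) if noise_sigma > 0 else 0.0
    profile = pd.DataFrame(
        {"distance": x, "intensity": np.clip(signal + baseline + noise, 0.0, None)}
    )
    background = pd.DataFrame({"distance": x, "intensity": np.full_like(x, baseline)})
    return profile, background
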