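"""Joint mechanics of bonded subunit dimers.

The ssDNA angle and bond modules make the joint between two rigid subunit
cores flexible: the binding angle of a dimer fluctuates thermally over a
broad, approximately Gaussian range.  This module provides the analysis
chain from raw observations to design conclusions:

* signed binding angles from face point clouds (principal-component face
  frames, as used on coarse-grained trajectory exports);
* Gaussian statistics of an angle ensemble (maximum-likelihood fit on raw
  samples, with a goodness-of-fit diagnostic);
* temperature rescaling of the spread, σ²(T₂)/σ²(T₁) = T₂/T₁, under the
  assumption of a temperature-independent harmonic spring — the correction
  applied to ensembles vitrified at ~136 K to report room temperature;
* the equipartition bending modulus k = (T/T₀)/σ_rad² in units of
  k_B·T₀/rad² (T₀ = 298 K);
* bend/twist/stretch mode decomposition of relative rigid-body poses;
* accessible-structure ranking: a candidate structure is energetically
  reachable when its target angle lies within c·σ of the joint's mean,
  and among reachable closed structures the smallest (largest angle)
  assembles first — the kinetic rule;
* gel densitometry yield: fitted target-peak Gaussian area over total
  lane area.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.transform import Rotation

from .geometry import BindingAngleSpec

__all__ = [
    "AngleEnsemble",
    "GaussianFit",
    "JointMechanics",
    "PosePair",
    "ModeDecomposition",
    "CandidateStructure",
    "RankedCandidate",
    "REFERENCE_T0",
    "VITRIFICATION_T",
    "dimer_angle_from_faces",
    "fit_gaussian",
    "rescale_sigma",
    "bending_modulus",
    "sigma_from_modulus",
    "decompose_modes",
    "accessible_structures",
    "gel_yield",
    "read_angle_csv",
    "read_coordinate_csv",
    "read_gel_csv",
]

REFERENCE_T0 = 298.0  # K, room temperature reference for moduli
VITRIFICATION_T = 136.0  # K, assumed vitrification temperature of water


class EnsembleSource(str, Enum):
    MEASURED = "measured"
    SIMULATED = "simulated"
    SYNTHETIC = "synthetic"


@dataclass
class AngleEnsemble:
    """Sampled signed binding angles (degrees) at a stated temperature."""

    angles: np.ndarray
    temperature: float
    source: EnsembleSource = EnsembleSource.SYNTHETIC

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        self.source = EnsembleSource(self.source)

    def __len__(self) -> int:
        return self.angles.size


@dataclass(frozen=True)
class GaussianFit:
    """Maximum-likelihood Gaussian fit of an angle ensemble.

    ``sigma`` uses the 1/n (ML) normalization.  ``ks_pvalue`` is a
    Kolmogorov-Smirnov diagnostic against the fitted normal; a tiny value
    flags a distribution the Gaussian summary misrepresents.
    """

    mean: float
    sigma: float
    n: int
    ks_statistic: float
    ks_pvalue: float

    def __iter__(self):
        return iter((self.mean, self.sigma))


@dataclass(frozen=True)
class JointMechanics:
    """Summary mechanics of a joint at a reference temperature."""

    mean_angle: float
    sigma: float
    temperature: float
    bending_modulus: float  # k_B·T0 per rad² at T0 = 298 K
    mode_variances: Optional[dict[str, float]] = None


def dimer_angle_from_faces(
    points_a: np.ndarray,
    points_b: np.ndarray,
    ref_vector: Sequence[float],
) -> float:
    """Signed binding angle (degrees) between two bonded face point sets.

    Each face's width and height axes are its top two principal components;
    the face normal is their cross product.  The two normals are oriented
    mutually facing (dot ≤ 0, valid for bonded pairs with |θ| < 90°); the
    magnitude is 180° minus the angle between them (coplanar facing rows
    give 0°), and the sign is the sign of (n_a × n_b)·ref_vector, with
    ``ref_vector`` the positive hinge direction (along the bonded edge) —
    a quantity invariant under the remaining simultaneous normal flip.
    Swapping the bodies flips the sign; rigidly moving the whole pair
    (and the reference direction with it) leaves the angle unchanged.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    ref = np.asarray(ref_vector, dtype=float)
    for pts in (a, b):
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
            raise ValueError("each face needs >= 3 points of dimension 3")

    def face_normal(pts: np.ndarray) -> np.ndarray:
        x = pts - pts.mean(axis=0)
        _, s, vt = np.linalg.svd(x, full_matrices=False)
        if s[1] < 1e-9 * max(s[0], 1.0):
            raise ValueError("degenerate (collinear) face point set")
        n = np.cross(vt[0], vt[1])
        return n / np.linalg.norm(n)

    na = face_normal(a)
    nb = face_normal(b)
    if np.dot(na, nb) > 0:
        nb = -nb
    cosang = float(np.clip(np.dot(na, nb), -1.0, 1.0))
    magnitude = 180.0 - math.degrees(math.acos(cosang))
    axis = np.cross(na, nb)
    sign = math.copysign(1.0, float(np.dot(axis, ref))) if np.linalg.norm(axis) > 1e-12 else 1.0
    return sign * magnitude


def fit_gaussian(ensemble: AngleEnsemble) -> GaussianFit:
    """ML Gaussian fit (sample mean, 1/n standard deviation) of an ensemble."""
    x = ensemble.angles
    if x.size < 2:
        raise ValueError("need at least 2 samples to fit")
    mean = float(np.mean(x))
    sigma = float(np.std(x))  # ddof=0: maximum-likelihood normalization
    if sigma == 0.0:
        warnings.warn("degenerate fit: all samples identical (sigma = 0)")
        return GaussianFit(mean, 0.0, x.size, ks_statistic=0.0, ks_pvalue=1.0)
    ks = stats.kstest((x - mean) / sigma, "norm")
    return GaussianFit(mean, sigma, x.size, float(ks.statistic), float(ks.pvalue))


def rescale_sigma(sigma: float, T_from: float, T_to: float) -> float:
    """Rescale an angular spread between temperatures: σ ∝ sqrt(T).

    Under a temperature-independent harmonic spring, σ²(T₂)/σ²(T₁) =
    T₂/T₁; the mean angle is unchanged by convention.  Used to bring
    spreads equilibrated at the vitrification temperature (136 K) to room
    temperature (298 K).
    """
    if T_from <= 0 or T_to <= 0:
        raise ValueError("temperatures must be positive (K)")
    return sigma * math.sqrt(T_to / T_from)


def bending_modulus(sigma: float, T: float = REFERENCE_T0) -> float:
    """Equipartition bending modulus, in k_B·T₀/rad² (T₀ = 298 K).

    For a harmonic bend with spread σ (degrees) observed at temperature T,
    k = (T/T₀)·1/σ_rad².  At T = T₀ this is simply 1/σ_rad².  The
    temperature-independent-spring assumption behind this estimate is
    first-order only; coarse-grained simulations show deviations from both
    purely entropic and temperature-independent behaviour.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    sigma_rad = math.radians(sigma)
    return (T / REFERENCE_T0) / sigma_rad**2


def sigma_from_modulus(modulus: float, T: float = REFERENCE_T0) -> float:
    """Inverse of :func:`bending_modulus`: σ (degrees) at temperature T."""
    if modulus <= 0:
        raise ValueError("modulus must be positive")
    return math.degrees(math.sqrt(T / (REFERENCE_T0 * modulus)))


# ---------------------------------------------------------------------------
# mode decomposition


@dataclass(frozen=True)
class PosePair:
    """Relative pose of body B with respect to body A.

    ``rotvec`` is the axis-angle rotation (radians, axis·angle vector) and
    ``translation`` the displacement (nm) of B's frame from its nominal
    bonded position.  Nominal axes: x along the hinge (bond edge), y along
    the face height (bottom row → top row), z along the bond separation.
    """

    rotvec: tuple[float, float, float]
    translation: tuple[float, float, float]


@dataclass
class ModeDecomposition:
    """PCA of 6-DOF pose fluctuations about the mean pose.

    Rotational components are in radians and translations in nm; the two
    are treated as commensurate in the PCA (1 rad ~ 1 nm), which is a
    simplified real-space stand-in for a full eigen-space calibration.
    """

    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # rows: PCs in (rx, ry, rz, tx, ty, tz)
    mode_variances: dict[str, float]
    pc1_angle_slope: float  # degrees of bend per unit PC1 score
    pc1_angle_intercept: float
    rank: int


def decompose_modes(poses: Sequence[PosePair]) -> ModeDecomposition:
    """Decompose pose fluctuations into bend/twist/stretch content.

    Builds the 6-DOF deviation matrix about the mean pose (mean rotation
    via the chordal average, mean translation), extracts principal
    components, and reports the variance of the projections onto the
    nominal bend (rotation about x), twist (rotation about z) and stretch
    (translation along z) axes, plus a linear map from PC1 score to bend
    angle in degrees.
    """
    if len(poses) < 3:
        raise ValueError("need >= 3 poses")
    rots = Rotation.from_rotvec([p.rotvec for p in poses])
    trans = np.asarray([p.translation for p in poses], dtype=float)
    mean_rot = rots.mean()
    dev_rot = (rots * mean_rot.inv()).as_rotvec()
    dev_trans = trans - trans.mean(axis=0)
    X = np.hstack([dev_rot, dev_trans])
    cov = np.cov(X, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    idx = np.argsort(evals)[::-1]
    evals = np.clip(evals[idx], 0.0, None)
    comps = evecs[:, idx].T
    tol = max(evals[0], 1e-30) * 1e-9
    rank = int(np.sum(evals > tol))
    if rank < 6:
        warnings.warn(f"degenerate pose covariance: rank {rank} < 6")
    mode_variances = {
        "bend": float(np.var(X[:, 0])),
        "twist": float(np.var(X[:, 2])),
        "stretch": float(np.var(X[:, 5])),
    }
    scores = X @ comps[0]
    bend_deg = np.degrees(X[:, 0])
    if np.ptp(scores) > 0:
        slope, intercept, *_ = stats.linregress(scores, bend_deg)
    else:
        slope, intercept = 0.0, float(bend_deg.mean())
    return ModeDecomposition(
        eigenvalues=evals,
        components=comps,
        mode_variances=mode_variances,
        pc1_angle_slope=float(slope),
        pc1_angle_intercept=float(intercept),
        rank=rank,
    )


# ---------------------------------------------------------------------------
# accessible structures


@dataclass(frozen=True)
class CandidateStructure:
    """A candidate closed (or open) structure a joint could assemble."""

    spec: BindingAngleSpec
    subunit_count: Optional[int]  # None for unbounded open structures

    @property
    def label(self) -> str:
        return self.spec.bond_class


@dataclass(frozen=True)
class RankedCandidate:
    candidate: CandidateStructure
    z_score: float
    accessible: bool
    rank: Optional[int]  # among accessible candidates; None if excluded


def accessible_structures(
    mean: float,
    sigma: float,
    candidates: Sequence[CandidateStructure],
    c_window: float = 2.5,
) -> list[RankedCandidate]:
    """Rank candidate structures by the energetic window and kinetic rule.

    Energetic condition: a candidate is accessible when its target angle
    lies within ``c_window``·σ of the joint's mean angle.  Kinetic rule:
    accessible candidates are ranked by ascending subunit count — the
    smallest closed structure (largest binding angle) assembles fastest
    and is preferred; unbounded open structures rank last.  Every
    candidate is annotated with its z-score.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not candidates:
        raise ValueError("empty candidate list")
    scored = []
    for cand in candidates:
        z = abs(cand.spec.theta_target - mean) / sigma
        scored.append((cand, z, z <= c_window))
    inf = float("inf")
    accessible = sorted(
        (t for t in scored if t[2]),
        key=lambda t: (t[0].subunit_count if t[0].subunit_count is not None else inf, t[1]),
    )
    ranks = {id(t[0]): i + 1 for i, t in enumerate(accessible)}
    out = [
        RankedCandidate(cand, z, ok, ranks.get(id(cand)))
        for cand, z, ok in scored
    ]
    out.sort(key=lambda r: (r.rank is None, r.rank if r.rank is not None else r.z_score))
    return out


# ---------------------------------------------------------------------------
# gel densitometry


class GelFitError(RuntimeError):
    """Target-peak Gaussian fit failed; carries diagnostics."""


def gel_yield(
    profile: pd.DataFrame,
    background: Optional[pd.DataFrame] = None,
    peak_window: Optional[tuple[float, float]] = None,
) -> float:
    """Assembly yield from a gel lane intensity profile.

    ``profile`` and ``background`` are two-column tables (distance,
    intensity) on the same grid.  The background-subtracted profile is
    normalized, a Gaussian is fitted to the target peak inside
    ``peak_window`` (default: whole lane), and the yield is the fitted
    Gaussian area divided by the total area — invariant under uniform
    intensity rescaling.
    """
    x = np.asarray(profile.iloc[:, 0], dtype=float)
    y = np.asarray(profile.iloc[:, 1], dtype=float)
    if background is not None:
        if len(background) != len(profile):
            raise ValueError("background and profile must have the same length")
        y = y - np.asarray(background.iloc[:, 1], dtype=float)
    y = np.clip(y, 0.0, None)
    total = float(np.trapezoid(y, x))
    if total <= 0:
        raise ValueError("non-positive total area after background subtraction")
    y = y / total  # normalize: yield is scale-invariant
    if peak_window is None:
        peak_window = (float(x.min()), float(x.max()))
    lo, hi = peak_window
    m = (x >= lo) & (x <= hi)
    if m.sum() < 5:
        raise GelFitError(f"peak window [{lo}, {hi}] contains {int(m.sum())} points")
    xw, yw = x[m], y[m]

    def gauss(t, amp, mu, sig):
        return amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)

    i0 = int(np.argmax(yw))
    p0 = [float(yw[i0]), float(xw[i0]), max((hi - lo) / 10.0, 1e-6)]
    try:
        popt, _ = optimize.curve_fit(gauss, xw, yw, p0=p0, maxfev=10_000)
    except RuntimeError as err:
        raise GelFitError(f"Gaussian fit did not converge: {err}") from err
    amp, mu, sig = popt
    sig = abs(sig)
    if amp <= 0 or not lo <= mu <= hi or sig > (hi - lo):
        raise GelFitError(
            f"no credible peak in window: amp={amp:.3g}, mu={mu:.3g}, sigma={sig:.3g}"
        )
    peak_area = float(amp * sig * math.sqrt(2.0 * math.pi))
    return min(peak_area, 1.0)


# ---------------------------------------------------------------------------
# tabular IO


def read_angle_csv(path) -> AngleEnsemble:
    """Read an angle list CSV with columns angle_deg, temperature_K."""
    df = pd.read_csv(path)
    if "angle_deg" not in df.columns:
        raise ValueError("angle CSV needs an 'angle_deg' column")
    temp = float(df["temperature_K"].iloc[0]) if "temperature_K" in df.columns else REFERENCE_T0
    return AngleEnsemble(df["angle_deg"].to_numpy(), temperature=temp,
                         source=EnsembleSource.MEASURED)


def read_coordinate_csv(path) -> pd.DataFrame:
    """Read a coordinate table CSV: body, point_id, x, y, z (+ optional sample)."""
    df = pd.read_csv(path)
    needed = {"body", "point_id", "x", "y", "z"}
    if not needed <= set(df.columns):
        raise ValueError(f"coordinate CSV needs columns {sorted(needed)}")
    return df


def read_gel_csv(path) -> pd.DataFrame:
    """Read a gel profile CSV: distance, intensity."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("gel CSV needs (distance, intensity) columns")
    return df
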