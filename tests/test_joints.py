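"""Joint mechanics: signed angles, Gaussian fits, moduli, ranking, gels."""

import math

import numpy as np
import pytest

from origamod.geometry import BindingAngleSpec
from origamod.joints import (
    AngleEnsemble,
    CandidateStructure,
    GelFitError,
    PosePair,
    accessible_structures,
    bending_modulus,
    decompose_modes,
    dimer_angle_from_faces,
    fit_gaussian,
    gel_yield,
    rescale_sigma,
    sigma_from_modulus,
)
from origamod.synthetic import default_face_template, synthetic_gel_profile

REF = np.array([1.0, 0.0, 0.0])  # hinge direction of the test fixtures


def hinged_pair(theta_deg, gap=2.0):
    """Two face point sets rotated by a known angle about the bottom hinge."""
    template = default_face_template()
    c, s = math.cos(math.radians(-theta_deg)), math.sin(math.radians(-theta_deg))
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    hinge = np.array([0.0, 0.0, gap / 2.0])
    b = (template + np.array([0.0, 0.0, gap]) - hinge) @ rot.T + hinge
    return template, b


class TestDimerAngle:
    def test_coplanar_parallel_faces_zero(self):
        a, b = hinged_pair(0.0)
        assert dimer_angle_from_faces(a, b, REF) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [30.0, 41.8, -19.7, 70.5])
    def test_known_hinge_rotation_recovered(self, theta):
        a, b = hinged_pair(theta)
        assert dimer_angle_from_faces(a, b, REF) == pytest.approx(theta, abs=1e-6)

    def test_antisymmetric_under_body_exchange(self):
        a, b = hinged_pair(30.0)
        forward = dimer_angle_from_faces(a, b, REF)
        backward = dimer_angle_from_faces(b, a, REF)
        assert backward == pytest.approx(-forward)

    def test_invariant_under_rigid_motion_of_pair(self):
        rng = np.random.default_rng(7)
        a, b = hinged_pair(25.0)
        for _ in range(5):
            rv = rng.normal(size=3)
            angle = np.linalg.norm(rv)
            axis = rv / angle
            K = np.array(
                [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
            )
            R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K
            t = rng.normal(size=3) * 10
            moved = dimer_angle_from_faces(a @ R.T + t, b @ R.T + t, R @ REF)
            assert moved == pytest.approx(25.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        line = np.array([[i, 0.0, 0.0] for i in range(5)])
        a, b = hinged_pair(10.0)
        with pytest.raises(ValueError, match="degenerate"):
            dimer_angle_from_faces(line, b, REF)


class TestGaussianFit:
    def test_sampling_oracle_recovery(self):
        rng = np.random.default_rng(42)
        ens = AngleEnsemble(rng.normal(21.6, 12.7, size=100_000), temperature=298.0)
        fit = fit_gaussian(ens)
        assert fit.mean == pytest.approx(21.6, rel=0.01)
        assert fit.sigma == pytest.approx(12.7, rel=0.01)

    def test_degenerate_samples_warn(self):
        ens = AngleEnsemble([5.0, 5.0, 5.0], temperature=298.0)
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_gaussian(ens)
        assert fit.sigma == 0.0

    def test_single_sample_refused(self):
        with pytest.raises(ValueError):
            fit_gaussian(AngleEnsemble([1.0], temperature=298.0))

    def test_bimodal_flagged_by_goodness_of_fit(self):
        rng = np.random.default_rng(3)
        mixture = np.concatenate(
            [rng.normal(-30, 2, 5000), rng.normal(30, 2, 5000)]
        )
        fit = fit_gaussian(AngleEnsemble(mixture, temperature=298.0))
        assert fit.sigma > 0  # a fit is still returned
        assert fit.ks_pvalue < 1e-6  # but flagged as non-Gaussian


class TestTemperatureRescaling:
    def test_vitrification_to_room(self):
        assert rescale_sigma(10.0, 136.0, 298.0) == pytest.approx(14.80, abs=0.01)

    def test_identity_and_round_trip(self):
        assert rescale_sigma(8.5, 200.0, 200.0) == 8.5
        assert rescale_sigma(
            rescale_sigma(8.5, 136.0, 298.0), 298.0, 136.0
        ) == pytest.approx(8.5)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            rescale_sigma(5.0, 0.0, 298.0)


class TestBendingModulus:
    def test_flexible_joint_modulus(self):
        # sigma = 12.7 deg at room temperature: ~20.4, printed as 20.5
        assert bending_modulus(12.7, 298.0) == pytest.approx(20.5, rel=0.01)

    def test_rigid_joint_modulus(self):
        assert bending_modulus(7.4, 298.0) == pytest.approx(59.3, rel=0.015)

    def test_unit_identity_one_radian(self):
        assert bending_modulus(math.degrees(1.0), 298.0) == pytest.approx(1.0)

    def test_commutes_with_rescaling(self):
        # rescaling the spread and re-applying equipartition describe the
        # same harmonic spring
        direct = bending_modulus(10.0, 136.0)
        rescaled = bending_modulus(rescale_sigma(10.0, 136.0, 298.0), 298.0)
        assert direct == pytest.approx(rescaled, rel=1e-12)

    def test_inverse(self):
        assert sigma_from_modulus(bending_modulus(12.7)) == pytest.approx(12.7)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            bending_modulus(0.0)


class TestModeDecomposition:
    def test_pure_hinge_rotation_is_bend_dominated(self):
        rng = np.random.default_rng(1)
        poses = [
            PosePair((math.radians(b), 0.0, 0.0), (0.0, 0.0, 0.0))
            for b in rng.normal(20, 10, 500)
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            md = decompose_modes(poses)
        assert md.eigenvalues[0] / md.eigenvalues.sum() >= 0.99
        assert abs(md.components[0][0]) > 0.99  # PC1 along the bend axis
        assert md.mode_variances["bend"] > 0
        assert md.mode_variances["twist"] == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_is_stretch_only(self):
        rng = np.random.default_rng(2)
        poses = [
            PosePair((0.0, 0.0, 0.0), (0.0, 0.0, s)) for s in rng.normal(0, 0.5, 300)
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            md = decompose_modes(poses)
        assert abs(md.components[0][5]) > 0.99
        assert md.mode_variances["stretch"] > 0
        assert md.mode_variances["bend"] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_rotational_noise_equal_eigenvalues(self):
        rng = np.random.default_rng(4)
        poses = [
            PosePair(tuple(rng.normal(0, 0.05, 3)), (0.0, 0.0, 0.0))
            for _ in range(4000)
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            md = decompose_modes(poses)
        rot_evals = md.eigenvalues[:3]
        assert rot_evals.max() / rot_evals.min() < 1.2

    def test_pc1_maps_linearly_to_bend_angle(self):
        rng = np.random.default_rng(5)
        poses = [
            PosePair((math.radians(b), 0.0, rng.normal(0, 0.01)), (0, 0, rng.normal(0, 0.05)))
            for b in rng.normal(20, 10, 1000)
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            md = decompose_modes(poses)
        assert abs(md.pc1_angle_slope) > 0

    def test_too_few_poses(self):
        with pytest.raises(ValueError):
            decompose_modes([PosePair((0, 0, 0), (0, 0, 0))] * 2)


CANDIDATES = [
    CandidateStructure(BindingAngleSpec("6-fold sheet", 0.0), None),
    CandidateStructure(BindingAngleSpec("icosahedron", 41.8), 20),
    CandidateStructure(BindingAngleSpec("octahedron", 70.5), 8),
]


class TestAccessibleStructures:
    def test_flexible_joint_selects_icosahedron_excludes_octahedron(self):
        ranking = accessible_structures(21.6, 12.7, CANDIDATES, c_window=2.5)
        by_label = {r.candidate.label: r for r in ranking}
        assert not by_label["octahedron"].accessible
        assert by_label["icosahedron"].accessible
        closed = [
            r for r in ranking if r.accessible and r.candidate.subunit_count is not None
        ]
        assert closed[0].candidate.label == "icosahedron"
        assert by_label["icosahedron"].z_score == pytest.approx(1.59, abs=0.01)
        assert by_label["octahedron"].z_score == pytest.approx(3.85, abs=0.01)

    def test_rigid_joint_only_planar_survives(self):
        ranking = accessible_structures(4.6, 7.4, CANDIDATES, c_window=2.5)
        accessible = [r.candidate.label for r in ranking if r.accessible]
        assert accessible == ["6-fold sheet"]

    def test_vanishing_sigma_keeps_only_exact_match(self):
        ranking = accessible_structures(41.8, 1e-9, [
            CandidateStructure(BindingAngleSpec("icosahedron", 41.8), 20),
            CandidateStructure(BindingAngleSpec("octahedron", 70.5), 8),
        ])
        accessible = [r.candidate.label for r in ranking if r.accessible]
        assert accessible == ["icosahedron"]

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            accessible_structures(0.0, 1.0, [])


class TestGelYield:
    def test_recovers_constructed_peak_fraction(self):
        profile, background = synthetic_gel_profile(0.62)
        y = gel_yield(profile, background, peak_window=(20.0, 40.0))
        assert y == pytest.approx(0.62, abs=0.01)

    def test_pure_gaussian_is_full_yield(self):
        profile, background = synthetic_gel_profile(1.0)
        assert gel_yield(profile, background, (20.0, 40.0)) == pytest.approx(1.0, abs=0.01)

    def test_profile_equal_to_background_rejected(self):
        _, background = synthetic_gel_profile(0.5)
        with pytest.raises(ValueError, match="total area"):
            gel_yield(background, background, (20.0, 40.0))

    def test_invariant_under_intensity_rescaling(self):
        profile, background = synthetic_gel_profile(0.4)
        scaled = profile.copy()
        scaled["intensity"] *= 37.0
        bg_scaled = background.copy()
        bg_scaled["intensity"] *= 37.0
        assert gel_yield(profile, background, (20.0, 40.0)) == pytest.approx(
            gel_yield(scaled, bg_scaled, (20.0, 40.0)), rel=1e-6
        )

    def test_no_peak_exercises_failure_path(self):
        profile, background = synthetic_gel_profile(0.0)
        with pytest.raises(GelFitError):
            gel_yield(profile, background, peak_window=(20.0, 40.0))
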