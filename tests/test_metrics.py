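from dataclasses import replace

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from needleplace import (
    AnalysisConfig,
    PointCloud,
    RigidTransform,
    SynthConfig,
    assess_trial,
    euclidean_distance,
    extract_tip,
    fit_needle_axis,
    generate_trial,
    lateral_depth,
    sample_surface,
)
from needleplace.metrics import AmbiguousAxisError


def _axis_from_z(tip_z: float = 0.0):
    """Needle axis along +z with the tip (s_max) at z = tip_z."""
    pts = np.column_stack(
        [np.zeros(501), np.zeros(501), np.linspace(tip_z - 50.0, tip_z, 501)]
    )
    return fit_needle_axis(pts, tip_hint=np.array([0.0, 0.0, tip_z]))


class TestFitNeedleAxis:
    def test_collinear_points(self):
        z = np.arange(5001) * 0.01
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        axis = fit_needle_axis(pts, tip_hint=np.array([0.0, 0.0, 100.0]))
        np.testing.assert_allclose(np.abs(axis.direction), [0, 0, 1], atol=1e-12)
        assert axis.direction[2] > 0  # tip orientation resolved toward hint
        assert axis.residual_rms_mm <= 1e-9
        np.testing.assert_allclose(axis.tip_point, [0, 0, 50.0], atol=1e-9)

    def test_cylinder_recovers_direction(self):
        rng = np.random.default_rng(0)
        true_dir = np.array([1.0, 2.0, 0.5])
        true_dir /= np.linalg.norm(true_dir)
        s = rng.uniform(0, 60, 20000)
        psi = rng.uniform(0, 2 * np.pi, 20000)
        # orthonormal frame
        a = np.cross(true_dir, [0, 0, 1.0])
        a /= np.linalg.norm(a)
        b = np.cross(true_dir, a)
        pts = s[:, None] * true_dir + 0.5 * (np.cos(psi)[:, None] * a + np.sin(psi)[:, None] * b)
        axis = fit_needle_axis(pts)
        cosang = abs(axis.direction @ true_dir)
        assert np.rad2deg(np.arccos(min(cosang, 1.0))) < 0.1

    def test_spherical_cloud_ambiguous(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((3000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        with pytest.raises(AmbiguousAxisError):
            fit_needle_axis(v)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_needle_axis(np.zeros((2, 3)))


class TestExtractTip:
    def test_outermost_five_mm_count(self):
        z = np.round(np.arange(0, 50.0 + 1e-9, 0.01), 10)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        axis = fit_needle_axis(pts, tip_hint=np.array([0, 0, 100.0]))
        tip = extract_tip(pts, axis, 5.0)
        assert len(tip) == 501
        assert tip[:, 2].min() >= 45.0 - 1e-9

    def test_tip_length_exceeding_needle(self):
        z = np.linspace(0, 10, 100)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        axis = fit_needle_axis(pts)
        assert len(extract_tip(pts, axis, 1000.0)) == 100

    def test_single_point_cloud(self):
        axis = _axis_from_z(0.0)
        single = np.array([[0.0, 0.0, 0.0]])
        out = extract_tip(single, axis, 5.0)
        np.testing.assert_array_equal(out, single)

    def test_invalid_tip_length(self):
        axis = _axis_from_z()
        with pytest.raises(ValueError):
            extract_tip(np.zeros((5, 3)), axis, 0.0)

    @pytest.mark.parametrize("lengths", [(1.0, 2.0, 5.0, 10.0, 60.0)])
    def test_monotone_in_tip_length(self, lengths):
        rng = np.random.default_rng(2)
        z = rng.uniform(0, 50, 3000)
        pts = np.column_stack([0.1 * rng.standard_normal((3000, 2)), z])
        axis = fit_needle_axis(pts, tip_hint=np.array([0, 0, 100.0]))
        counts = [len(extract_tip(pts, axis, L)) for L in lengths]
        assert counts == sorted(counts)


class TestEuclideanDistance:
    def test_pythagoras(self):
        assert euclidean_distance(np.array([[0.0, 0, 0]]), np.array([[3.0, 4, 0]])) == 5.0

    def test_touching_point(self):
        nerve = np.array([[1.0, 1, 1], [2.0, 2, 2]])
        assert euclidean_distance(np.array([[2.0, 2, 2]]), nerve) == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.uniform(-50, 50, (200, 3))
            b = rng.uniform(-50, 50, (200, 3))
            assert euclidean_distance(a, b) == cdist(a, b).min()

    def test_empty_inputs(self):
        with pytest.raises(ValueError):
            euclidean_distance(np.zeros((0, 3)), np.ones((2, 3)))

    def test_minimality(self):
        rng = np.random.default_rng(4)
        tip = rng.uniform(0, 10, (50, 3))
        nerve = rng.uniform(5, 15, (60, 3))
        d = euclidean_distance(tip, nerve)
        for i in range(0, 50, 7):
            for j in range(0, 60, 11):
                assert d <= np.linalg.norm(tip[i] - nerve[j]) + 1e-12


class TestLateralDepth:
    def test_closed_form_undershoot(self):
        axis = _axis_from_z(0.0)
        t = np.linspace(-20, 20, 401)
        nerve = np.column_stack([t, np.full_like(t, 3.0), np.full_like(t, 4.0)])
        lat, dep, foot, ncp = lateral_depth(axis, nerve, lateral_ref=[0, 1, 0])
        assert abs(abs(lat) - 3.0) <= 1e-9
        assert abs(dep - 4.0) <= 1e-9
        assert lat > 0  # nerve on +y side of the axis
        np.testing.assert_allclose(foot, [0, 0, 4.0], atol=1e-9)
        np.testing.assert_allclose(ncp, [0, 3.0, 4.0], atol=1e-9)
        # tip at (0,0,0): euclidean closes the Pythagorean triangle
        assert abs(euclidean_distance(np.array([[0.0, 0, 0]]), nerve) - 5.0) <= 1e-9

    def test_closed_form_overshoot_sign(self):
        axis = _axis_from_z(0.0)
        t = np.linspace(-20, 20, 401)
        nerve = np.column_stack([t, np.full_like(t, 3.0), np.full_like(t, -4.0)])
        _, dep, _, _ = lateral_depth(axis, nerve, lateral_ref=[0, 1, 0])
        assert abs(dep - (-4.0)) <= 1e-9  # deeper than target -> negative

    def test_nerve_point_on_axis(self):
        axis = _axis_from_z(0.0)
        nerve = np.array([[0.0, 0.0, -7.0]])
        lat, dep, _, _ = lateral_depth(axis, nerve, lateral_ref=[0, 1, 0])
        assert lat == 0.0
        assert abs(dep - (-7.0)) <= 1e-9

    def test_ill_conditioned_reference(self):
        axis = _axis_from_z()
        with pytest.raises(ValueError, match="ill-conditioned"):
            lateral_depth(axis, np.array([[1.0, 0, 0]]), lateral_ref=[0.01, 0, 1.0])

    def test_unsigned_when_no_reference(self):
        axis = _axis_from_z()
        lat, _, _, _ = lateral_depth(axis, np.array([[0.0, -3.0, 0.0]]))
        assert lat == 3.0


class TestMetricProperties:
    def test_pythagorean_identity_noiseless(self, clean_trial):
        ref = sample_surface(clean_trial.nerve, 0.2)
        cfg = AnalysisConfig(spacing_mm=0.2, tip_mode="extreme_point")
        res = assess_trial(clean_trial, ref, cfg, nerve_target=clean_trial.truth.nerve_centerline)
        lhs = res.euclidean_mm**2
        rhs = res.lateral_mm**2 + res.depth_mm**2
        assert abs(lhs - rhs) <= 1e-6

    def test_rigid_invariance_pure_metrics(self):
        """Common rigid motion of needle cloud, nerve cloud and sign reference
        leaves all three metrics unchanged (no registration involved)."""
        rng = np.random.default_rng(5)
        z = np.linspace(-50, 0, 2000)
        needle = np.column_stack([0.2 * rng.standard_normal((2000, 2)), z])
        t = np.linspace(-20, 20, 500)
        nerve = np.column_stack([t, np.full_like(t, 3.0), np.full_like(t, 4.0)])
        ref_vec = np.array([0.0, 1.0, 0.0])

        def metrics(needle_pts, nerve_pts, ref):
            axis = fit_needle_axis(needle_pts, tip_hint=needle_pts[np.argmax(needle_pts @ axis0_dir)])
            lat, dep, _, _ = lateral_depth(axis, nerve_pts, ref)
            eu = euclidean_distance(extract_tip(needle_pts, axis, 5.0), nerve_pts)
            return np.array([eu, lat, dep])

        axis0_dir = np.array([0.0, 0.0, 1.0])
        base = metrics(needle, nerve, ref_vec)
        T = RigidTransform(
            Rotation.from_euler("xyz", [30, -20, 45], degrees=True).as_matrix(),
            np.array([12.0, -7.0, 3.0]),
        )
        axis0_dir = T.rotation @ axis0_dir
        moved = metrics(T.apply(needle), T.apply(nerve), T.rotation @ ref_vec)
        assert np.abs(base - moved).max() <= 1e-6

    def test_assess_identity_registration(self, clean_trial):
        """Trial == reference: assess_trial metrics equal the directly
        computed ones exactly (ICP returns the identity)."""
        ref = sample_surface(clean_trial.nerve, 0.25)
        cfg = AnalysisConfig(spacing_mm=0.25)
        res = assess_trial(clean_trial, ref, cfg)
        needle_cloud = sample_surface(clean_trial.needle, 0.25)
        axis = fit_needle_axis(needle_cloud, tip_hint=clean_trial.truth.tip_point)
        tip = extract_tip(needle_cloud, axis, 5.0)
        eu = euclidean_distance(tip, ref)
        lat, dep, _, _ = lateral_depth(axis, ref)
        assert res.euclidean_mm == eu
        assert res.lateral_mm == abs(lat)
        assert res.depth_mm == abs(dep)
        assert res.icp_iterations == 1

    def test_within_range_flags_strict(self, clean_trial):
        ref = sample_surface(clean_trial.nerve, 0.3)
        res = assess_trial(clean_trial, ref, AnalysisConfig(spacing_mm=0.3))
        assert res.within_range_euclidean == (res.euclidean_mm < 5.0)
        assert res.within_range_lateral == (res.lateral_mm < 5.0)
        assert res.within_range_depth == (res.depth_mm < 5.0)

    def test_jitter_recovered_by_registration(self, clean_trial):
        cfg = SynthConfig(pose_jitter_rot_deg=10, pose_jitter_trans_mm=20)
        rec = generate_trial(cfg, "trial_001", seed=77)
        ref = sample_surface(clean_trial.nerve, 0.25)
        acfg = AnalysisConfig(spacing_mm=0.25)
        base = assess_trial(clean_trial, ref, acfg)
        moved = assess_trial(rec, ref, acfg, reference_landmarks=clean_trial.landmarks)
        assert abs(moved.euclidean_mm - base.euclidean_mm) <= 1e-3
        assert abs(moved.lateral_mm - base.lateral_mm) <= 1e-3
        assert abs(moved.depth_mm - base.depth_mm) <= 1e-3
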