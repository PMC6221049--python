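import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import tmsfmri as tf
from tmsfmri import coil

params_st = st.lists(
    st.floats(-40, 40, allow_nan=False, allow_infinity=False),
    min_size=6, max_size=6,
)


def _markers_dict(model, pose):
    return {k: pose.apply(v) for k, v in model.template_markers.items()}


class TestFitCoilPose:
    def test_identity_when_observed_equals_template(self):
        model = coil.default_coil_model()
        pose, rms = coil.fit_coil_pose(dict(model.template_markers), model)
        assert pose.is_identity(tol=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-12)

    @given(params_st)
    def test_round_trip_recovers_known_pose(self, p):
        model = coil.default_coil_model()
        true = tf.RigidTransform.from_params(p)
        fit, rms = coil.fit_coil_pose(_markers_dict(model, true), model)
        assert np.allclose(fit.as_matrix(), true.as_matrix(), atol=1e-9)
        assert rms < 1e-9

    def test_rms_matches_independent_kabsch(self):
        """Perturbing one marker: rotation and residual agree with scipy's
        independent Kabsch solver (Rotation.align_vectors)."""
        model = coil.default_coil_model()
        true = tf.RigidTransform.from_params([4.0, -2.0, 7.0, 12.0, -5.0, 30.0])
        obs = _markers_dict(model, true)
        obs["m2"] = obs["m2"] + np.array([1.0, 0.0, 0.0])
        fit, rms = coil.fit_coil_pose(obs, model)

        P = model.marker_array()
        Q = np.stack([obs[k] for k in model.template_markers])
        cP, cQ = P.mean(0), Q.mean(0)
        rot, _ = Rotation.align_vectors(Q - cQ, P - cP)
        R = rot.as_matrix()
        t = cQ - R @ cP
        resid = (P @ R.T + t) - Q
        rms_oracle = np.sqrt(np.mean(np.sum(resid ** 2, axis=1)))
        assert rms == pytest.approx(rms_oracle, abs=1e-9)
        assert np.allclose(fit.rotation, R, atol=1e-9)

    @given(params_st)
    def test_residual_invariant_to_common_frame_change(self, p):
        model = coil.default_coil_model()
        true = tf.RigidTransform.from_params([3, 1, -2, 5, 10, -4])
        obs = _markers_dict(model, true)
        rng = np.random.default_rng(0)
        for k in obs:
            obs[k] = obs[k] + rng.normal(0, 0.5, 3)
        _, rms1 = coil.fit_coil_pose(obs, model)
        frame = tf.RigidTransform.from_params(p)
        obs2 = {k: frame.apply(v) for k, v in obs.items()}
        _, rms2 = coil.fit_coil_pose(obs2, model)
        assert rms1 == pytest.approx(rms2, abs=1e-8)

    def test_rotation_always_proper_under_noise(self):
        model = coil.default_coil_model()
        true = tf.RigidTransform.from_params([0, 0, 0, 0, 175, 0])
        for seed in range(25):
            rng = np.random.default_rng(seed)
            obs = {k: v + rng.normal(0, 2.0, 3)
                   for k, v in _markers_dict(model, true).items()}
            fit, _ = coil.fit_coil_pose(obs, model)
            assert np.linalg.det(fit.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        model = coil.default_coil_model()
        with pytest.raises(ValueError, match="at least 3"):
            coil.fit_coil_pose({"m1": np.zeros(3), "m2": np.ones(3)}, model)
        collinear = {f"m{i+1}": np.array([float(i), 0.0, 0.0]) for i in range(6)}
        with pytest.raises(ValueError, match="collinear"):
            coil.fit_coil_pose(collinear, model)


class TestProjectIsocenter:
    def test_identity_pose_returns_offset(self):
        model = coil.CoilModel(coil.default_coil_model().template_markers,
                               isocenter_offset=(0, 0, -20))
        iso = coil.project_isocenter(tf.RigidTransform.identity(), model)
        assert np.allclose(iso, [0, 0, -20])

    def test_translation_equivariance(self):
        model = coil.default_coil_model()
        t = np.array([5.0, -7.0, 2.0])
        pose = tf.RigidTransform(np.eye(3), t)
        assert np.allclose(coil.project_isocenter(pose, model),
                           model.isocenter_offset + t)

    def test_quarter_turn_about_z(self):
        model = coil.CoilModel(coil.default_coil_model().template_markers,
                               isocenter_offset=(10, 0, 0))
        pose = tf.RigidTransform.from_params([1.0, 2.0, 3.0, 0, 0, 90.0])
        assert np.allclose(coil.project_isocenter(pose, model),
                           np.array([0, 10, 0]) + np.array([1.0, 2.0, 3.0]),
                           atol=1e-12)


class TestTrackIsocenter:
    def test_no_motion_track_is_constant(self):
        iso = np.array([-40.0, 25.0, 50.0])
        transforms = [tf.RigidTransform.identity()] * 10
        track = coil.track_isocenter(iso, None, transforms)
        assert np.allclose(track.per_volume_isocenter, iso)
        assert track.max_displacement == pytest.approx(0.0)

    def test_single_translated_volume(self):
        iso = np.array([0.0, 0.0, 60.0])
        transforms = [tf.RigidTransform.identity() for _ in range(5)]
        transforms[3] = tf.RigidTransform(np.eye(3), np.array([2.0, 0.0, 0.0]))
        track = coil.track_isocenter(iso, None, transforms)
        d = np.linalg.norm(track.per_volume_isocenter[3]
                           - track.per_volume_isocenter[0])
        assert d == pytest.approx(2.0, abs=1e-12)

    def test_epi_to_anat_conjugation(self):
        """With a pure-translation coregistration the track displacements
        are unchanged (conjugation by a translation)."""
        iso = np.array([10.0, -5.0, 40.0])
        transforms = [tf.RigidTransform.from_params([0.5 * k, 0, 0, 0, 0, 0])
                      for k in range(4)]
        t1 = coil.track_isocenter(iso, None, transforms)
        A = np.eye(4); A[:3, 3] = [100.0, -50.0, 30.0]
        t2 = coil.track_isocenter(iso, A, transforms)
        assert np.allclose(t1.displacements, t2.displacements, atol=1e-9)

    def test_non_invertible_affine_rejected(self):
        A = np.zeros((4, 4))
        with pytest.raises(ValueError, match="not invertible"):
            coil.track_isocenter(np.zeros(3), A, [tf.RigidTransform.identity()])

    def test_round_trip_through_realignment(self):
        """Synthetic motion -> realign -> track recovers the true
        motion-induced isocenter excursion."""
        from tmsfmri import preproc, synth
        spec = tf.PhantomSpec(grid_shape=(16, 16, 16), n_dynamics=6,
                              noise_sd=0, drift_amplitude=0, effect_pct=0, seed=21)
        s, _, _ = tf.generate_phantom(spec)
        s = preproc.smooth(s, 6.0)
        mp = np.zeros((6, 6))
        mp[2] = [1.5, -0.5, 0.5, 0.5, 0, 0]
        mp[4] = [-1.0, 1.0, 0.0, 0, -0.5, 0.5]
        moved = synth.apply_motion(s, mp)
        rr = preproc.realign(moved, reference="first")
        iso = np.array([-40.0, 25.0, 50.0])
        track = coil.track_isocenter(iso, None, rr.transforms)
        c = s.world_center
        truth_pts = np.array([
            tf.RigidTransform.from_params(p, center=c).inverse().apply(iso)
            for p in mp
        ])
        truth_track = coil.CoilTrack.from_points(truth_pts)
        assert track.max_displacement == pytest.approx(
            truth_track.max_displacement, abs=0.3)


class TestSummarizeTrack:
    def test_single_point(self):
        track = coil.CoilTrack.from_points([[1.0, 2.0, 3.0]])
        s = coil.summarize_track(track)
        assert (s["cog_x_mm"], s["cog_y_mm"], s["cog_z_mm"]) == (1.0, 2.0, 3.0)
        assert s["max_displacement_mm"] == 0.0

    def test_two_points_six_mm_apart(self):
        track = coil.CoilTrack.from_points([[0, 0, 0], [6.0, 0, 0]])
        assert coil.summarize_track(track)["max_displacement_mm"] == 3.0

    @given(params_st)
    def test_cog_translation_equivariant_displacement_invariant(self, p):
        rng = np.random.default_rng(5)
        pts = rng.normal(0, 3, (12, 3))
        T = tf.RigidTransform.from_params(p)
        t1 = coil.CoilTrack.from_points(pts)
        t2 = coil.CoilTrack.from_points(T.apply(pts))
        assert np.allclose(t2.cog, T.apply(t1.cog), atol=1e-8)
        assert t2.max_displacement == pytest.approx(t1.max_displacement, abs=1e-8)

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            coil.CoilTrack.from_points(np.empty((0, 3)))
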