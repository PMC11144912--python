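"""Segment frames, Cardan angle algebra, joint angle curves, normalization,
and event summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from ovigait.events import GaitCycle, detect_events, qc_cycles, segment_cycles
from ovigait.kinematics import (JointAngleSeries, SegmentModel, build_frames,
                                cardan_compose, cardan_decompose,
                                joint_angles, mean_curve, normalize_to_cycle,
                                relative_rotation, segment_basis,
                                summarize_events)
from ovigait.markers import Limb, lowpass_filter, mirror_sagittal
from ovigait.synthetic import synthesize_static, synthesize_trial


def random_rotations(n, seed=0, beta_max=80.0):
    rng = np.random.default_rng(seed)
    angles = np.column_stack([rng.uniform(-179, 179, n),
                              rng.uniform(-beta_max, beta_max, n),
                              rng.uniform(-179, 179, n)])
    return angles, cardan_compose(angles)


class TestCardan:
    def test_identity(self):
        np.testing.assert_allclose(cardan_decompose(np.eye(3)), [0, 0, 0],
                                   atol=1e-12)

    @pytest.mark.parametrize("axis,expected", [
        (0, (45.0, 0.0, 0.0)), (1, (0.0, 45.0, 0.0)), (2, (0.0, 0.0, 45.0))])
    def test_single_axis_rotation(self, axis, expected):
        angles = np.zeros(3)
        angles[axis] = 45.0
        np.testing.assert_allclose(cardan_decompose(cardan_compose(angles)),
                                   expected, atol=1e-12)

    def test_round_trip_1000_random_rotations(self):
        angles, R = random_rotations(1000, seed=12)
        back = cardan_compose(cardan_decompose(R, warn_gimbal=False))
        assert np.max(np.linalg.norm(R - back, axis=(1, 2))) < 1e-9

    def test_against_scipy_euler_convention(self):
        # independent cross-check of the closed-form decomposition
        angles, R = random_rotations(200, seed=5)
        scipy_R = Rotation.from_euler("XYZ", angles, degrees=True).as_matrix()
        np.testing.assert_allclose(R, scipy_R, atol=1e-12)
        scipy_angles = Rotation.from_matrix(R).as_euler("XYZ", degrees=True)
        np.testing.assert_allclose(cardan_decompose(R, warn_gimbal=False),
                                   scipy_angles, atol=1e-9)

    def test_gimbal_proximity_warns(self):
        with pytest.warns(UserWarning, match="gimbal"):
            cardan_decompose(cardan_compose(np.array([10.0, 88.0, 10.0])))

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None)
    def test_decompose_recompose_property(self, seed):
        _angles, R = random_rotations(1, seed=seed)
        back = cardan_compose(cardan_decompose(R[0], warn_gimbal=False))
        assert np.linalg.norm(R[0] - back) < 1e-9


class TestRelativeRotation:
    def test_identical_frames_give_identity(self):
        _a, R = random_rotations(10, seed=3)
        rel = relative_rotation(R, R)
        np.testing.assert_allclose(rel, np.tile(np.eye(3), (10, 1, 1)),
                                   atol=1e-12)

    def test_constructed_pure_x_rotation(self):
        _a, P = random_rotations(5, seed=4)
        Rx = cardan_compose(np.array([30.0, 0.0, 0.0]))
        D = np.einsum("nij,jk->nik", P, Rx)
        rel = relative_rotation(P, D)
        np.testing.assert_allclose(rel, np.tile(Rx, (5, 1, 1)), atol=1e-9)

    def test_chain_composition_identity(self):
        _x, A = random_rotations(7, seed=6)
        _y, B = random_rotations(7, seed=7)
        _z, C = random_rotations(7, seed=8)
        lhs = relative_rotation(A, C)
        rhs = np.einsum("nij,njk->nik", relative_rotation(A, B),
                        relative_rotation(B, C))
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestSegmentFrames:
    def test_axis_aligned_construction(self):
        basis = segment_basis(np.array([[0.0, 0, 0]]), np.array([[0.0, 0, 1]]),
                              np.array([[0.1, 0, 0.5]]), plane_sign=1.0)[0]
        np.testing.assert_allclose(basis[:, 2], [0, 0, 1], atol=1e-9)  # Z
        # plane normal (Z x v) defines Y; X completes the right-handed triad
        np.testing.assert_allclose(basis[:, 1], [0, 1, 0], atol=1e-9)
        np.testing.assert_allclose(basis[:, 0], [1, 0, 0], atol=1e-9)
        assert np.linalg.det(basis) == pytest.approx(1.0, abs=1e-12)

    def test_collinear_markers_name_frame(self):
        with pytest.raises(ValueError, match="frame 0"):
            segment_basis(np.array([[0.0, 0, 0]]), np.array([[0.0, 0, 1]]),
                          np.array([[0.0, 0, 0.5]]), segment="thigh")

    def test_orthonormal_det_plus_one_everywhere(self, ref_trial, lmap):
        mset, _ = ref_trial
        frames = build_frames(lowpass_filter(mset, 10.0), lmap,
                              SegmentModel("right"))
        for f in frames.values():
            B = f.basis
            gram = np.einsum("nij,nik->njk", B, B)
            assert np.max(np.abs(gram - np.eye(3))) < 1e-9
            assert np.allclose(np.linalg.det(B), 1.0, atol=1e-9)

    def test_basis_continuity_during_walking(self, ref_trial, lmap):
        mset, _ = ref_trial
        frames = build_frames(lowpass_filter(mset, 10.0), lmap,
                              SegmentModel("right"))
        for f in frames.values():
            rel = relative_rotation(f.basis[:-1], f.basis[1:])
            tr = np.einsum("nii->n", rel)
            step = np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1)))
            assert step.max() < 30.0

    def test_equivariance_under_rigid_rotation(self, clean_trial, lmap):
        mset, _ = clean_trial
        model = SegmentModel("right")
        base = build_frames(mset, lmap, model)
        R = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        moved = build_frames(mset.transformed(rotation=R, translation=[1, 2, 0]),
                             lmap, model)
        for name in base:
            np.testing.assert_allclose(
                moved[name].basis, np.einsum("ij,njk->nik", R, base[name].basis),
                atol=1e-9)

    def test_generator_standing_posture_frames(self, ref_config, lmap):
        static, _angles = synthesize_static(ref_config)
        frames = build_frames(static, lmap, SegmentModel("right"))
        mset, truth = synthesize_trial(ref_config)
        for seg in ("pelvis", "thigh", "shank", "metatarsus"):
            # static frames are constant and orthonormal
            B = frames[seg].basis
            assert np.max(np.abs(B - B[0])) < 1e-12
        # frame recovery on the dynamic noise-free trial
        clean = truth.clean_set
        dyn = build_frames(clean, lmap, SegmentModel("right"))
        for seg in ("pelvis", "thigh", "shank", "metatarsus"):
            diff = relative_rotation(dyn[seg].basis,
                                     truth.rotations[("right", seg)])
            tr = np.einsum("nii->n", diff)
            ang = np.degrees(np.arccos(np.clip((tr - 1) / 2, -1, 1)))
            assert ang.max() < 0.1

    def test_missing_landmark_names_side_and_landmark(self, ref_trial):
        from ovigait.markers import LandmarkMap
        mset, _ = ref_trial
        partial = LandmarkMap({"R_coxal_tuberosity":
                               ("right", "coxal_tuberosity")})
        with pytest.raises(KeyError, match="right.*ischial"):
            build_frames(mset, partial, SegmentModel("right"))


class TestJointAngles:
    def test_static_self_reference_is_zero(self, ref_config, lmap):
        static, _ = synthesize_static(ref_config)
        model = SegmentModel("right")
        frames = build_frames(static, lmap, model)
        angles = joint_angles(frames, model, static=frames)
        for s in angles.values():
            assert s.reference == "static-offset"
            assert np.max(np.abs(s.data)) < 1e-9

    def test_prescribed_knee_flexion_recovered(self, ref_config, lmap):
        from dataclasses import replace
        anchors = {j: {c: [(0.0, 0.0)] for c in comps}
                   for j, comps in ref_config.joint_anchor_angles.items()}
        anchors["knee"]["flexion_extension"] = [(0.0, 47.0)]
        cfg = replace(ref_config, joint_anchor_angles=anchors)
        static, _ = synthesize_static(cfg)
        model = SegmentModel("right")
        angles = joint_angles(build_frames(static, lmap, model), model)
        knee = angles["knee"].data
        assert knee[:, 0] == pytest.approx(47.0, abs=0.1)
        assert np.max(np.abs(knee[:, 1:])) < 0.5

    def test_noise_free_curve_rmse_below_02_deg(self, clean_trial, lmap,
                                                clean_config):
        mset, truth = clean_trial
        model = SegmentModel("right")
        angles = joint_angles(build_frames(mset, lmap, model), model)
        psi = np.mod(mset.time / clean_config.cycle_time, 1.0)
        for joint in ("hip", "knee", "ankle"):
            rmse = np.sqrt(np.mean(
                (angles[joint].data - truth.joint_curve(joint, psi)) ** 2))
            assert rmse < 0.2

    def test_noisy_filtered_curve_rmse_below_2_deg(self, ref_trial, lmap,
                                                   ref_config):
        mset, truth = ref_trial
        model = SegmentModel("right")
        filtered = lowpass_filter(mset, 10.0)
        angles = joint_angles(build_frames(filtered, lmap, model), model)
        psi = np.mod(mset.time / ref_config.cycle_time, 1.0)
        for joint in ("hip", "knee", "ankle"):
            rmse = np.sqrt(np.mean(
                (angles[joint].data - truth.joint_curve(joint, psi)) ** 2))
            assert rmse < 2.0

    def test_knee_flexion_at_ic_near_reference_value(self, ref_trial, lmap):
        mset, _ = ref_trial
        filtered = lowpass_filter(mset, 10.0)
        model = SegmentModel("right")
        angles = joint_angles(build_frames(filtered, lmap, model), model)
        cycles = [c for c in qc_cycles(
            segment_cycles(detect_events(mset, lmap)), mset, lmap)
            if c.valid and c.limb == Limb("right", "hind")]
        ic_vals = [normalize_to_cycle(angles["knee"], c, mset.rate).data[0, 0]
                   for c in cycles]
        assert np.mean(ic_vals) == pytest.approx(46.869, abs=2.0)

    def test_mirrored_trial_negates_non_sagittal_components(self, clean_trial,
                                                            lmap):
        mset, _ = clean_trial
        mirrored = mirror_sagittal(mset)
        right = joint_angles(build_frames(mset, lmap, SegmentModel("right")),
                             SegmentModel("right"), clinical_signs=False)
        left = joint_angles(build_frames(mirrored, lmap, SegmentModel("left")),
                            SegmentModel("left"), clinical_signs=False)
        for joint in ("hip", "knee", "ankle"):
            np.testing.assert_allclose(
                left[joint].data,
                right[joint].data * np.array([1.0, -1.0, -1.0]), atol=1e-6)

    def test_unwrapped_components_have_no_jumps(self, ref_trial, lmap):
        mset, _ = ref_trial
        model = SegmentModel("right")
        angles = joint_angles(build_frames(lowpass_filter(mset, 10.0), lmap,
                                           model), model)
        for s in angles.values():
            assert np.max(np.abs(np.diff(s.data, axis=0))) < 180.0


class TestNormalization:
    def make_series(self, data):
        return JointAngleSeries("knee", data, rate=100.0)

    def test_constant_input(self):
        s = self.make_series(np.full((200, 3), 10.0))
        cycle = GaitCycle(Limb("right", "hind"), 20, 80, 120)
        norm = normalize_to_cycle(s, cycle, 100.0)
        assert norm.data.shape == (101, 3)
        np.testing.assert_allclose(norm.data, 10.0)

    def test_linear_ramp_is_exact(self):
        ramp = np.linspace(0, 100, 101)
        data = np.stack([ramp, ramp, ramp], axis=1)
        s = self.make_series(data)
        cycle = GaitCycle(Limb("right", "hind"), 0, 60, 100)
        norm = normalize_to_cycle(s, cycle, 100.0)
        np.testing.assert_allclose(norm.data[:, 0], np.arange(101), atol=1e-9)

    def test_cosine_against_analytic_values(self):
        t = np.arange(121) / 100.0
        cyc_t = 1.0
        vals = np.cos(2 * np.pi * t / cyc_t)
        s = self.make_series(np.stack([vals] * 3, axis=1))
        cycle = GaitCycle(Limb("right", "hind"), 0, 60, 100)
        norm = normalize_to_cycle(s, cycle, 100.0)
        analytic = np.cos(2 * np.pi * np.linspace(0, 1, 101))
        assert np.max(np.abs(norm.data[:, 0] - analytic)) < np.deg2rad(0.05) * 180 / np.pi

    def test_cycle_outside_span_rejected(self):
        s = self.make_series(np.zeros((50, 3)))
        with pytest.raises(ValueError, match="span"):
            normalize_to_cycle(s, GaitCycle(Limb("right", "hind"), 10, 40, 60),
                               100.0)


class TestEventSummary:
    def norm_series(self, values):
        data = np.stack([values] * 3, axis=1)
        return JointAngleSeries("knee", data, normalized=True,
                                stance_fraction=0.6)

    def test_monotone_profile(self):
        s = self.norm_series(np.linspace(0, 100, 101))
        summ = summarize_events(s)
        m = summ.mean["flexion_extension"]
        assert m["STANCEmax"] == m["TO"] == pytest.approx(60.0)
        assert m["SWINGmax"] == pytest.approx(100.0)
        assert m["IC"] == m["STANCEmin"] == 0.0

    def test_sine_profile_extrema(self):
        grid = np.linspace(0, 1, 101)
        s = self.norm_series(np.sin(2 * np.pi * grid))
        summ = summarize_events(s, stance_fraction=0.6)
        m = summ.mean["flexion_extension"]
        assert m["STANCEmax"] == pytest.approx(1.0, abs=1e-3)   # at t=0.25
        assert m["SWINGmin"] == pytest.approx(-1.0, abs=1e-3)   # at t=0.75
        assert summ.sd["flexion_extension"]["IC"] == 0.0

    def test_stance_swing_extrema_ordering_invariant(self, ref_trial, lmap):
        mset, _ = ref_trial
        model = SegmentModel("right")
        angles = joint_angles(build_frames(lowpass_filter(mset, 10.0),
                                           lmap, model), model)
        cycles = [c for c in qc_cycles(
            segment_cycles(detect_events(mset, lmap)), mset, lmap)
            if c.valid and c.limb == Limb("right", "hind")]
        norm = [normalize_to_cycle(angles["ankle"], c, mset.rate)
                for c in cycles]
        summ = summarize_events(norm)
        for comp in JointAngleSeries.COMPONENTS:
            assert summ.mean[comp]["STANCEmin"] <= summ.mean[comp]["STANCEmax"]
            assert summ.mean[comp]["SWINGmin"] <= summ.mean[comp]["SWINGmax"]

    def test_mean_curve_averages_cycles(self):
        a = self.norm_series(np.zeros(101))
        b = self.norm_series(np.ones(101) * 10)
        avg = mean_curve([a, b])
        np.testing.assert_allclose(avg.data, 5.0)
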