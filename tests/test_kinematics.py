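"""Virtual ASIS reconstruction, COM, angles, events and per-cycle indices."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gazeassist as ga
from gazeassist import kinematics as kin
from gazeassist import preprocess as pp
from gazeassist import synthetic_data as sd
from gazeassist.anthropometry import Segment, SegmentSet, default_segments
from gazeassist.core import (
    ALL_MARKERS,
    ForcePlateSeries,
    MarkerTrajectorySet,
    ValidationError,
)


def _single_frame(markers: dict) -> MarkerTrajectorySet:
    names = tuple(markers)
    pos = np.array([[markers[m] for m in names]], dtype=float)
    return MarkerTrajectorySet(names, pos, 100.0)


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.normal(0, 1.0, 3)
    return R.as_matrix(), t


class TestVirtualASIS:
    JIG = {"SJ1": [0.0, -0.12, 0.05], "SJ2": [0.07, -0.17, 0.09],
           "SJ3": [-0.06, -0.16, 0.15]}

    def _static(self, lasi, rasi):
        return _single_frame({**self.JIG, "LASI": lasi, "RASI": rasi})

    def test_asis_coincident_with_jig_marker_gives_zero_offset(self):
        pose = kin.calibrate_virtual_asis(
            self._static(self.JIG["SJ1"], [0.11, 0.10, 0.02])
        )
        assert np.allclose(pose.offset_lasi, 0.0, atol=1e-12)

    def test_offsets_invariant_under_rigid_motion_of_static_pose(self, rng):
        static = self._static([-0.11, 0.10, 0.02], [0.11, 0.10, 0.02])
        pose0 = kin.calibrate_virtual_asis(static)
        R, t = _random_rigid(rng)
        moved = MarkerTrajectorySet(
            static.marker_names, static.positions @ R.T + t, 100.0
        )
        pose1 = kin.calibrate_virtual_asis(moved)
        assert np.allclose(pose0.offset_lasi, pose1.offset_lasi, atol=1e-12)
        assert np.allclose(pose0.offset_rasi, pose1.offset_rasi, atol=1e-12)

    def test_reconstruction_matches_rigid_transform_oracle(self, rng):
        """Random rigid motions of jig+ASIS: reconstructed ASIS within 1e-9 m
        of truth, cross-checked against an explicit Procrustes-style oracle."""
        lasi, rasi = np.array([-0.11, 0.10, 0.02]), np.array([0.11, 0.10, 0.02])
        static = self._static(lasi, rasi)
        pose = kin.calibrate_virtual_asis(static)
        n = 50
        frames = {m: np.empty((n, 3)) for m in static.marker_names}
        truth_l = np.empty((n, 3))
        for i in range(n):
            R, t = _random_rigid(rng)
            for m in self.JIG:
                frames[m][i] = R @ self.JIG[m] + t
            truth_l[i] = R @ lasi + t
            frames["LASI"][i] = np.nan  # occluded; must be reconstructed
            frames["RASI"][i] = R @ rasi + t
        names = tuple(frames)
        moving = MarkerTrajectorySet(
            names, np.stack([frames[m] for m in names], axis=1), 100.0
        )
        out, report = kin.reconstruct_asis(moving, pose)
        assert np.max(np.abs(out.get("LASI") - truth_l)) < 1e-9
        # visible RASI is untouched and its virtual twin agrees
        assert report["RASI_rms_discrepancy_m"] < 1e-9
        assert report["LASI_filled"] == n

    def test_identity_motion_virtual_equals_measured(self):
        static = self._static([-0.11, 0.10, 0.02], [0.11, 0.10, 0.02])
        pose = kin.calibrate_virtual_asis(static)
        out, report = kin.reconstruct_asis(static.copy(), pose)
        assert np.allclose(out.get("LASI"), static.get("LASI"))
        assert report["LASI_rms_discrepancy_m"] < 1e-12

    def test_collinear_jig_rejected(self):
        bad = _single_frame({
            "SJ1": [0, 0, 0], "SJ2": [0, 0, 0.1], "SJ3": [0, 0, 0.2],
            "LASI": [0.1, 0, 0], "RASI": [-0.1, 0, 0],
        })
        with pytest.raises(ValidationError, match="collinear"):
            kin.calibrate_virtual_asis(bad)

    def test_occluded_span_reconstructed_continuously(self, skeleton):
        """A scripted lean occludes the ASIS for a stretch; the virtual track
        must be continuous and exact at zero noise."""
        script = sd.MotionScript(n_cycles=1)
        markers = sd.generate_motion(script, skeleton)
        clean = sd.generate_motion(script, skeleton, occlusion_threshold_deg=1e9)
        assert np.isnan(markers.get("LASI")).any()
        pose = kin.calibrate_virtual_asis(sd.generate_static(skeleton))
        out, _ = kin.reconstruct_asis(markers, pose)
        err = np.max(np.abs(out.get("LASI") - clean.get("LASI")))
        assert err < 1e-3  # < 1 mm at zero noise
        assert not np.isnan(out.get("LASI")).any()


class TestWholeBodyCOM:
    def test_all_segment_coms_at_one_point(self, rng):
        p = rng.normal(0, 1, 3)
        markers = _single_frame({m: p for m in ALL_MARKERS})
        com = kin.whole_body_com(markers)
        assert np.allclose(com[0], p, atol=1e-12)

    def test_two_equal_mass_segments(self):
        segs = SegmentSet([
            Segment("a", 0.5, ("A1",), ("A2",), 0.5),
            Segment("b", 0.5, ("B1",), ("B2",), 0.5),
        ])
        markers = _single_frame({
            "A1": [0, 0, 0], "A2": [0, 0, 0],
            "B1": [1, 0, 0], "B2": [1, 0, 0],
        })
        com = kin.whole_body_com(markers, segs)
        assert np.allclose(com[0], [0.5, 0, 0])

    def test_random_pose_equals_direct_weighted_sum(self, rng):
        pos = rng.normal(0, 0.5, (7, len(ALL_MARKERS), 3))
        markers = MarkerTrajectorySet(ALL_MARKERS, pos, 100.0)
        com = kin.whole_body_com(markers)
        # independent brute-force summation oracle
        names = list(ALL_MARKERS)
        expected = np.zeros((7, 3))
        for seg in default_segments():
            prox = np.mean([pos[:, names.index(m)] for m in seg.proximal], axis=0)
            dist = np.mean([pos[:, names.index(m)] for m in seg.distal], axis=0)
            expected += seg.mass_fraction * (
                (1 - seg.com_fraction) * prox + seg.com_fraction * dist
            )
        assert np.allclose(com, expected, atol=1e-12)

    def test_rigid_transform_equivariance(self, rng, standing_markers):
        com0 = kin.whole_body_com(standing_markers)
        R, t = _random_rigid(rng)
        moved = MarkerTrajectorySet(
            standing_markers.marker_names,
            standing_markers.positions @ R.T + t, 100.0,
        )
        com1 = kin.whole_body_com(moved)
        assert np.allclose(com1, com0 @ R.T + t, atol=1e-10)

    def test_mass_fractions_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            SegmentSet([Segment("a", 0.5, ("A",), ("B",), 0.5)])

    def test_missing_landmark_error_names_segment(self, standing_markers):
        broken = standing_markers.copy()
        broken.get("LHEE")[:] = np.nan
        with pytest.raises(ValidationError, match="foot_l"):
            kin.whole_body_com(broken)


class TestTrunkAngle:
    def test_upright_trunk_is_zero(self, standing_markers):
        assert np.allclose(kin.trunk_angle(standing_markers), 0.0, atol=1e-9)

    def test_constructed_30_degree_forward_rotation(self, standing_markers):
        R = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        pos = standing_markers.positions @ R.T
        rotated = MarkerTrajectorySet(standing_markers.marker_names, pos, 100.0)
        assert np.allclose(kin.trunk_angle(rotated), 30.0, atol=1e-9)

    def test_cardan_x_component_vs_rotation_matrix_oracle(self, standing_markers):
        # explicit X-Y-Z Cardan composition as the independent oracle
        ax, ay, az = np.radians([10.0, 5.0, 5.0])
        Rx = np.array([[1, 0, 0], [0, np.cos(ax), -np.sin(ax)],
                       [0, np.sin(ax), np.cos(ax)]])
        Ry = np.array([[np.cos(ay), 0, np.sin(ay)], [0, 1, 0],
                       [-np.sin(ay), 0, np.cos(ay)]])
        Rz = np.array([[np.cos(az), -np.sin(az), 0],
                       [np.sin(az), np.cos(az), 0], [0, 0, 1]])
        R = Rx @ Ry @ Rz
        pos = standing_markers.positions @ R.T
        rotated = MarkerTrajectorySet(standing_markers.marker_names, pos, 100.0)
        assert np.allclose(kin.trunk_angle(rotated), 10.0, atol=1e-6)


def _rear_series(signal, rate=100.0):
    forces = np.zeros((signal.size, 2, 3))
    forces[:, 0, 2] = 0.5 * signal
    forces[:, 1, 2] = 0.5 * signal
    return ForcePlateSeries(("fp5", "fp6"), forces, rate,
                            rear_plates=("fp5", "fp6"))


class TestSeatOff:
    def test_clean_roundtrip_epsilon_zero(self, short_script):
        grf = sd.generate_grf(short_script)  # zero noise, 1,000 Hz
        times = kin.detect_seat_off(grf, epsilon_n=0.0)
        assert times == pytest.approx(short_script.seat_off_times, abs=1e-9)

    def test_linear_ramp_epsilon_crossing_vs_brute_force(self):
        t = np.arange(0, 3.0, 0.01)
        f = np.clip(200.0 * (2.0 - t), 0.0, 200.0)
        got = kin.detect_seat_off(_rear_series(f), epsilon_n=5.0)
        # brute-force scan with linear interpolation, sample by sample
        expected = None
        for i in range(1, t.size):
            if f[i] <= 5.0 < f[i - 1]:
                expected = t[i - 1] + (f[i - 1] - 5.0) / (f[i - 1] - f[i]) * 0.01
                break
        assert expected == pytest.approx(1.975)
        assert got[0] == pytest.approx(expected, abs=1e-9)

    def test_extrapolation_refines_crossing_to_zero_newton_instant(self):
        t = np.arange(0, 3.0, 0.01)
        f = np.clip(200.0 * (2.0 - t), 0.0, 200.0)
        got = kin.detect_seat_off(_rear_series(f), epsilon_n=5.0,
                                  refine="extrapolate")
        assert got[0] == pytest.approx(2.0, abs=1e-6)

    def test_force_never_unloading_raises(self):
        with pytest.raises(kin.EventDetectionError, match="no seat-off"):
            kin.detect_seat_off(_rear_series(np.full(500, 300.0)))

    def test_expected_cycle_count_enforced(self, short_script):
        grf = sd.generate_grf(short_script)
        with pytest.raises(kin.EventDetectionError, match="expected 5"):
            kin.detect_seat_off(grf, expected_cycles=5)

    def test_noisy_detection_unbiased_within_10ms(self, short_script, rng):
        """Monte-Carlo: 2 N sensor noise, full sync+filter chain, the
        detected seat-off stays within +/-10 ms of the scripted instant."""
        markers = sd.generate_motion(short_script)
        errs = []
        for _ in range(100):
            grf = sd.generate_grf(short_script, rng=rng, noise_sd_n=2.0)
            grf = pp.filter_grf(pp.synchronize(grf, markers))
            t_hat = kin.detect_seat_off(grf)[0]
            errs.append(t_hat - short_script.seat_off_times[0])
        assert abs(np.mean(errs)) < 0.010


class TestMaxDorsiflexionAndIndices:
    def test_monotone_rise_to_plateau_returns_first_plateau_sample(self):
        t = np.arange(0, 3.0, 0.01)
        angle = np.minimum(t * 10.0, 12.0)  # plateau from t = 1.2
        got = kin.detect_max_dorsiflexion(angle, t, 0.5, 3.0)
        assert got == pytest.approx(1.2, abs=1e-9)

    def test_scripted_unimodal_peak_roundtrip(self):
        t = np.arange(0, 4.0, 0.01)
        angle = -((t - 2.40) ** 2)
        assert kin.detect_max_dorsiflexion(angle, t, 1.0, 4.0) == pytest.approx(2.40)

    def test_noisy_series_equals_brute_force_argmax(self, rng):
        t = np.arange(0, 4.0, 0.01)
        angle = np.sin(t) + rng.normal(0, 0.05, t.size)
        got = kin.detect_max_dorsiflexion(angle, t, 0.3, 3.9)
        mask = (t > 0.3) & (t <= 3.9)
        best, best_t = -np.inf, None
        for ti, ai in zip(t[mask], angle[mask]):  # exhaustive scan oracle
            if ai > best:
                best, best_t = ai, ti
        assert got == best_t

    def test_com_velocity_arithmetic(self):
        t = np.arange(0, 1.0, 0.01)
        com = np.zeros((t.size, 3))
        assert kin.com_velocity(com, t, 0.2, 0.5) == 0.0
        com[:, 1] = 0.4 * t  # advances 0.10 m in 0.25 s
        assert kin.com_velocity(com, t, 0.5, 0.75) == pytest.approx(0.40)
        with pytest.raises(ValidationError):
            kin.com_velocity(com, t, 0.5, 0.5)

    def test_com_bos_signed_distance(self, standing_markers):
        com = kin.whole_body_com(standing_markers)
        t0 = standing_markers.times[0]
        got = kin.com_bos_distance(standing_markers, com, t0)
        heel_y = min(standing_markers.get("LHEE")[0, 1],
                     standing_markers.get("RHEE")[0, 1])
        assert got == pytest.approx(com[0, 1] - heel_y, abs=1e-12)
        # COM directly above the heel line -> 0; 23 mm behind -> -0.023
        com0 = com.copy()
        com0[:, 1] = heel_y
        assert kin.com_bos_distance(standing_markers, com0, t0) == pytest.approx(0.0)
        com0[:, 1] = heel_y - 0.023
        assert kin.com_bos_distance(standing_markers, com0, t0) == pytest.approx(-0.023)

    def test_deepest_flexion_constant_and_exhaustive_max(self, rng):
        t = np.arange(0, 5.0, 0.01)
        assert kin.deepest_trunk_flexion(np.full(t.size, 10.0), t, (0, 5)) == 10.0
        noisy = np.sin(t) * 30 + rng.normal(0, 0.5, t.size)
        got = kin.deepest_trunk_flexion(noisy, t, (0.5, 4.5))
        mask = (t >= 0.5) & (t <= 4.5)
        assert got == max(noisy[mask])  # brute-force max

    def test_event_ordering_per_cycle(self, clean_trial):
        idx = ga.trial_kinematic_indices(clean_trial)
        assert np.all(idx.max_dorsiflexion_times_s > idx.seat_off_times_s)


class TestRoundTrip:
    def test_noise_free_indices_match_script(self, clean_trial, short_script):
        """Full pipeline on a clean trial recovers the scripted values:
        0.1 deg flexion, 10 ms seat-off, 1 mm COM excursion."""
        idx = ga.trial_kinematic_indices(clean_trial)
        assert idx.deepest_trunk_flexion_deg == pytest.approx(41.0, abs=0.1)
        assert idx.seat_off_times_s == pytest.approx(
            short_script.seat_off_times, abs=0.010
        )
        window = idx.max_dorsiflexion_times_s[0] - idx.seat_off_times_s[0]
        excursion_err = abs(
            idx.com_velocity_ms * window - 0.436 * short_script.dorsi_peak_offset_s
        )
        assert excursion_err < 0.001
        assert idx.com_bos_distance_m == pytest.approx(-0.023, abs=0.001)
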