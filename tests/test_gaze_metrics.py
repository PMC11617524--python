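"""I-VT fixation detection, AOI bands and the four gaze metrics."""

import numpy as np
import pytest

import gazeassist as ga
from gazeassist import gaze_metrics as gm
from gazeassist import synthetic_data as sd
from gazeassist.core import AOI_NAMES, Fixation, GazeStream, ValidationError


def _stream(points, rate=50.0, validity=None):
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    validity = np.ones(n, dtype=bool) if validity is None else validity
    return GazeStream(np.arange(n) * 1000.0 / rate, points, validity, rate)


def _brute_force_ivt(stream, thr_dps=30.0, min_ms=60.0, dist=1.0):
    """Independent sample-by-sample velocity scan."""
    t, p, v = stream.timestamps_ms, stream.points, stream.validity
    n = len(t)
    slow = []
    for i in range(n - 1):
        d = np.hypot(p[i + 1, 0] - p[i, 0], p[i + 1, 1] - p[i, 1])
        ang = np.degrees(2 * np.arctan2(d, 2 * dist))
        vel = ang / ((t[i + 1] - t[i]) / 1000.0)
        slow.append(vel < thr_dps and v[i] and v[i + 1])
    dt = np.median(np.diff(t))
    out = []
    i = 0
    while i < n - 1:
        if slow[i]:
            j = i
            while j < n - 1 and slow[j]:
                j += 1
            dur = (j - i + 1) * dt
            if dur >= min_ms:
                out.append((t[i], dur))
            i = j
        else:
            i += 1
    return out


class TestDetectFixations:
    def test_constant_500ms_gives_one_full_fixation(self):
        fixs = gm.detect_fixations(_stream(np.tile([0.1, 1.0], (25, 1))))
        assert len(fixs) == 1
        assert fixs[0].duration_ms == pytest.approx(500.0)
        assert fixs[0].centroid == pytest.approx((0.1, 1.0))

    def test_alternating_large_jumps_yield_no_fixations(self):
        pts = np.array([[0.0, 0.0], [0.5, 0.5]] * 20)
        assert gm.detect_fixations(_stream(pts)) == []

    def test_stream_shorter_than_minimum_is_empty_not_error(self):
        assert gm.detect_fixations(_stream(np.zeros((2, 2)))) == []
        assert gm.detect_fixations(_stream(np.zeros((0, 2)))) == []

    def test_short_dwell_below_minimum_discarded(self):
        pts = np.vstack([
            np.tile([0.0, 0.0], (2, 1)),      # 40 ms < 60 ms minimum
            [[0.7, 0.7]],
            np.tile([0.1, 0.1], (10, 1)),     # 200 ms, kept
        ])
        fixs = gm.detect_fixations(_stream(pts))
        assert len(fixs) == 1
        assert fixs[0].duration_ms == pytest.approx(200.0)

    def test_invalid_samples_break_runs(self):
        pts = np.tile([0.0, 0.0], (20, 1))
        val = np.ones(20, dtype=bool)
        val[10] = False
        fixs = gm.detect_fixations(_stream(pts, validity=val))
        assert len(fixs) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_random_piecewise_streams_match_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        chunks = []
        for _ in range(rng.integers(3, 10)):
            point = rng.uniform(-0.5, 1.5, 2)
            chunks.append(np.tile(point, (rng.integers(1, 12), 1)))
        pts = np.vstack(chunks) + rng.normal(0, 1e-4, (sum(map(len, chunks)), 2))
        stream = _stream(pts)
        got = gm.detect_fixations(stream)
        expected = _brute_force_ivt(stream)
        assert len(got) == len(expected)
        for f, (start, dur) in zip(got, expected):
            assert f.start_ms == pytest.approx(start)
            assert f.duration_ms == pytest.approx(dur)


class TestAOILayout:
    def test_vertex_gaze_classified_head(self, standing_markers):
        layout = gm.build_aoi_layout(standing_markers)
        vertex = np.nanmean(
            [standing_markers.get(m)[0, 2]
             for m in ("LFHD", "RFHD", "LBHD", "RBHD")]
        )
        assert layout.label_points([vertex + 0.02], [0.0])[0] == "head"

    def test_boundary_point_belongs_to_upper_band(self, standing_markers):
        layout = gm.build_aoi_layout(standing_markers)
        t50 = layout.bounds["trunk"][0][0]  # trunk's lower bound at frame 0
        assert layout.label_points([t50], [0.0])[0] == "trunk"
        acro = layout.bounds["neck"][0][0]
        assert layout.label_points([acro], [0.0])[0] == "neck"

    def test_bands_pairwise_disjoint_under_motion(self, skeleton):
        script = sd.MotionScript(n_cycles=1)
        markers = sd.generate_motion(script, skeleton,
                                     occlusion_threshold_deg=1e9)
        layout = gm.build_aoi_layout(markers)
        names = list(AOI_NAMES)
        for i, a in enumerate(names):
            lo_a, hi_a = layout.bounds[a]
            assert np.all(lo_a < hi_a)
            for b in names[i + 1:]:
                lo_b, hi_b = layout.bounds[b]
                overlap = np.minimum(hi_a, hi_b) - np.maximum(lo_a, lo_b)
                assert np.all(overlap <= 1e-12)

    def test_random_points_match_brute_force_band_test(self, skeleton, rng):
        script = sd.MotionScript(n_cycles=1)
        markers = sd.generate_motion(script, skeleton,
                                     occlusion_threshold_deg=1e9)
        layout = gm.build_aoi_layout(markers)
        t = rng.uniform(0, markers.times[-1], 200)
        v = rng.uniform(-0.1, 1.8, 200)
        got = layout.label_points(v, t)
        for k in range(200):  # exhaustive per-point oracle
            frame = markers.frame_at(t[k])
            label = ""
            for name in AOI_NAMES:
                lo, hi = layout.bounds[name]
                if lo[frame] <= v[k] < hi[frame]:
                    label = name
                    break
            assert got[k] == label


class TestSupportPeriod:
    def test_scripted_window_returned_exactly(self, clean_trial):
        clean_trial.meta["support_window_s"] = [1.0, 8.2]
        assert gm.support_period(clean_trial) == (1.0, 8.2)

    def test_onset_detection_equals_brute_force_scan(self, clean_trial):
        import gazeassist.kinematics as kin

        meta = dict(clean_trial.meta)
        meta.pop("support_window_s")
        trial = ga.TrialDataset(clean_trial.markers, clean_trial.grf,
                                clean_trial.gaze, clean_trial.static, meta)
        w0, w1 = gm.support_period(trial)
        assert w1 == meta["hand_release_s"]
        angle = kin.trunk_angle(trial.markers)
        vel = np.abs(np.gradient(angle, 0.01))
        expected = None  # brute-force first-exceedance scan
        for i in range(vel.size):
            if vel[i] > gm.DEFAULT_ONSET_ANGVEL_DPS:
                expected = trial.markers.times[i]
                break
        assert w0 == expected
        assert w0 == pytest.approx(1.0, abs=0.2)  # scripted lean onset at 1.0 s

    def test_window_outside_recording_rejected(self, clean_trial):
        clean_trial.meta["support_window_s"] = [0.0, 1e4]
        with pytest.raises(ValidationError, match="outside"):
            gm.support_period(clean_trial)


def _static_layout(markers):
    return gm.build_aoi_layout(markers)


def _fix(start_s, dur_s, v):
    return Fixation(1000.0 * start_s, 1000.0 * dur_s, (0.0, v))


class TestMetrics:
    @pytest.fixture
    def layout(self, standing_markers):
        # stretch the static capture to cover a 10 s window
        m = standing_markers
        pos = np.repeat(m.positions[:1], 1001, axis=0)
        return _static_layout(
            ga.MarkerTrajectorySet(m.marker_names, pos, 100.0)
        )

    @pytest.fixture
    def anchors(self, layout):
        out = {}
        for a in AOI_NAMES:
            lo, hi = (b[0] for b in layout.bounds[a])
            out[a] = lo + 0.1 if a == "head" else (hi - 0.05 if a == "foot"
                                                   else 0.5 * (lo + hi))
        return out

    def test_total_duration_pct_empty_and_full(self, layout, anchors):
        window = (0.0, 10.0)
        assert gm.total_duration_pct([], layout, window)["head"] == 0.0
        full = [_fix(0.0, 10.0, anchors["head"])]
        out = gm.total_duration_pct(full, layout, window)
        assert out["head"] == pytest.approx(100.0)
        assert all(out[a] == 0.0 for a in AOI_NAMES if a != "head")

    def test_n_fixations_counts_labels(self, layout, anchors):
        window = (0.0, 10.0)
        fixs = [_fix(0.5, 0.2, anchors["head"]), _fix(1.0, 0.2, anchors["head"]),
                _fix(2.0, 0.2, anchors["knee"])]
        out = gm.n_fixations(fixs, layout, window)
        assert out == {"head": 2, "knee": 1, "neck": 0, "trunk": 0,
                       "hip": 0, "foot": 0}

    def test_mean_fixation_per_visit_hand_enumerated(self, layout, anchors):
        # A(100), A(100), B(50), A(300) -> A visits {200, 300} mean 250; B 50
        a, b = anchors["head"], anchors["trunk"]
        fixs = [_fix(0.0, 0.1, a), _fix(0.15, 0.1, a),
                _fix(0.30, 0.05, b), _fix(0.40, 0.3, a)]
        out = gm.mean_fixation_per_visit(fixs, layout, (0.0, 10.0))
        assert out["head"] == pytest.approx(250.0)
        assert out["trunk"] == pytest.approx(50.0)
        assert np.isnan(out["foot"])  # zero visits -> metric absent

    def test_latency_first_fixation(self, layout, anchors):
        fixs = [_fix(1.0, 0.2, anchors["foot"]), _fix(3.5, 0.2, anchors["head"]),
                _fix(4.0, 0.2, anchors["head"])]
        out = gm.latency_first_fixation(fixs, layout, (1.0, 10.0))
        assert out["foot"] == pytest.approx(0.0)      # at window start
        assert out["head"] == pytest.approx(2500.0)
        assert np.isnan(out["neck"])
        # brute-force first-occurrence scan
        labels = gm.assign_aoi(fixs, layout)
        for aoi in AOI_NAMES:
            first = next((f for f, lab in zip(fixs, labels) if lab == aoi), None)
            if first is not None:
                assert out[aoi] == first.start_ms - 1000.0

    def test_dwell_sums_bounded_and_time_shift_invariant(self, layout, anchors, rng):
        window = (0.0, 10.0)
        fixs = []
        t = 0.1
        for _ in range(20):
            aoi = list(AOI_NAMES)[rng.integers(0, 6)]
            dur = float(rng.uniform(0.06, 0.4))
            fixs.append(_fix(t, dur, anchors[aoi]))
            t += dur + 0.1
        out = gm.total_duration_pct(fixs, layout, window)
        assert sum(out.values()) <= 100.0 + 1e-9
        counts = gm.n_fixations(fixs, layout, window)
        # n_fixations >= n_visits >= 1 whenever dwell > 0
        visits = gm._visits(gm.assign_aoi(fixs, layout),
                            [f.duration_ms for f in fixs])
        for a in AOI_NAMES:
            if out[a] > 0:
                assert counts[a] >= len(visits[a]) >= 1
        # uniform time shift of fixations and window leaves metrics unchanged
        shift = 2.0
        shifted = [Fixation(f.start_ms + 1000 * shift, f.duration_ms, f.centroid)
                   for f in fixs]
        out2 = gm.total_duration_pct(shifted, layout, (shift, 10.0 + shift))
        assert out2 == pytest.approx(out)
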