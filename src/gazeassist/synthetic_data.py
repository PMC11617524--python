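"""Synthetic assisted sit-to-stand trials with known ground truth.

Generates cohorts of trials (markers at 100 Hz, force plates at 1,000 Hz,
gaze at 50 Hz) whose pipeline-derived kinematic indices and AOI gaze
metrics follow configurable group-level distributions. Defaults encode the
study conditions: 7 expert and 17 novice participants, 5 consecutive
stand/sit cycles per trial, group-conditioned distributions of deepest
trunk flexion, COM velocity, COM-BOS distance and per-AOI gaze behaviour.

The motion model is a planar (sagittal) articulated chain driven by
minimum-jerk joint profiles; lateral coordinates stay near-constant. Every
quantity the reported indices depend on is scripted: the rear plates
unload to exactly 0 N at the scripted seat-off, the trunk holds its
scripted peak flexion briefly before seat-off, and the whole-body COM is
shaped to move at exactly the scripted forward velocity between seat-off
and maximum ankle dorsiflexion while passing through the scripted COM-BOS
anchor (see ``_apply_com_targets``).

Nonnegative gaze quantities (dwell percentages, fixation counts) are drawn
from moment-matched gamma distributions, so configured group means are
reproduced exactly in expectation even when the sd is comparable to the
mean; signed or strictly-positive kinematic quantities use normals.
70% of each group variance is allocated between participants and 30%
within (configurable): the tables report only pooled spreads.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from . import gaze_metrics as gm
from . import kinematics
from .anthropometry import SegmentSet, default_segments, shift_sensitivity
from .core import (
    ALL_MARKERS,
    AOI_NAMES,
    ForcePlateSeries,
    GazeStream,
    MarkerTrajectorySet,
    TrialDataset,
    ValidationError,
    require,
    split_seed,
)

G_ACCEL = 9.80665

# markers that ride along with the above-knee forward shift used to realize
# scripted COM targets; knee/shank/foot markers stay put so ankle and knee
# geometry (and the heel line) are untouched
_SHIFT_MARKERS = frozenset(
    m for m in ALL_MARKERS
    if m[1:] not in ("KNE", "TIB", "ANK", "HEE", "TOE")
)

_MIN_FIX_SAMPLES = 3  # 60 ms at 50 Hz, exactly the I-VT minimum duration


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class AOIGazeParams:
    """Per-AOI dwell (% of support period) and fixation-count distribution."""

    dwell_pct_mean: float
    dwell_pct_sd: float
    n_fix_mean: float
    n_fix_sd: float

    def __post_init__(self):
        require(self.dwell_pct_sd >= 0 and self.n_fix_sd >= 0, "sds must be >= 0")
        require(0 <= self.dwell_pct_mean <= 100, "dwell % must lie in [0, 100]")
        require(self.n_fix_mean >= 0, "fixation count mean must be >= 0")


@dataclass(frozen=True)
class GroupParams:
    """Group-level distributions of the kinematic indices and gaze profile."""

    trunk_angle_mean_deg: float
    trunk_angle_sd_deg: float
    com_bos_mean_m: float          # signed; negative = COM behind the heel line
    com_bos_sd_m: float
    com_velocity_mean_ms: float
    com_velocity_sd_ms: float
    aoi_gaze_profile: dict = field(default_factory=dict)

    def __post_init__(self):
        require(
            min(self.trunk_angle_sd_deg, self.com_bos_sd_m,
                self.com_velocity_sd_ms) >= 0,
            "sds must be >= 0",
        )
        total = sum(p.dwell_pct_mean for p in self.aoi_gaze_profile.values())
        require(total <= 100.0, "per-AOI dwell fractions must sum to <= 100%")


def default_group_params() -> dict:
    """The default expert/novice study conditions."""
    expert_gaze = {
        "head": AOIGazeParams(10.75, 6.66, 25.71, 13.27),
        "neck": AOIGazeParams(6.72, 5.77, 17.29, 13.20),
        "trunk": AOIGazeParams(3.61, 3.20, 7.43, 6.37),
        "hip": AOIGazeParams(1.03, 1.27, 2.57, 3.02),
        "knee": AOIGazeParams(6.32, 5.52, 14.57, 10.62),
        "foot": AOIGazeParams(0.82, 1.00, 2.86, 3.36),
    }
    novice_gaze = {
        "head": AOIGazeParams(4.06, 6.68, 8.65, 13.73),
        "neck": AOIGazeParams(4.65, 4.50, 12.18, 14.74),
        "trunk": AOIGazeParams(6.15, 5.21, 12.18, 9.71),
        "hip": AOIGazeParams(3.63, 4.05, 6.65, 17.73),
        "knee": AOIGazeParams(5.34, 5.92, 9.12, 11.13),
        "foot": AOIGazeParams(0.93, 1.58, 2.00, 2.99),
    }
    return {
        "expert": GroupParams(41.0, 2.1, -0.023, 0.003, 0.436, 0.026,
                              expert_gaze),
        "novice": GroupParams(37.8, 3.7, -0.047, 0.032, 0.492, 0.067,
                              novice_gaze),
    }


@dataclass
class CohortConfig:
    """Cohort layout, group distributions and noise levels.

    A fixed seed yields byte-identical output; the seed is split
    hierarchically per participant/trial/stream, so adding a participant
    leaves the others' draws unchanged.
    """

    n_expert: int = 7
    n_novice: int = 17
    trials_per_participant: int = 5
    group_params: dict = field(default_factory=default_group_params)
    seed: int = 0
    between_participant_frac: float = 0.7
    marker_noise_sd_m: float = 0.0005
    grf_noise_sd_n: float = 2.0
    gaze_jitter_sd_m: float = 0.0005
    body_mass_kg: float = 60.0
    stature_m: float = 1.65

    def __post_init__(self):
        require(self.trials_per_participant >= 1, "trials per participant >= 1")
        require(self.n_expert >= 0 and self.n_novice >= 0, "counts must be >= 0")
        require(self.n_expert + self.n_novice >= 1, "cohort must have participants")
        require(0.0 <= self.between_participant_frac <= 1.0,
                "variance split must lie in [0, 1]")

    def groups(self):
        if self.n_expert:
            yield "expert", self.n_expert
        if self.n_novice:
            yield "novice", self.n_novice


@dataclass
class SkeletonModel:
    """Segment lengths and marker offsets of the collaborator's body.

    Lengths scale with stature; the chair height is an absolute lab
    dimension (0.415 m). 34 body markers + 3 sacral-jig markers.
    """

    stature_m: float = 1.65
    mass_kg: float = 60.0
    chair_height_m: float = 0.415

    def __post_init__(self):
        require(self.stature_m > 0 and self.mass_kg > 0,
                "stature and mass must be positive")
        s = self.stature_m / 1.65
        self.scale = s
        self.ankle_z = 0.08 * s
        self.shank_len = 0.41 * s
        self.thigh_len = 0.40 * s
        self.pelvis_up = 0.05 * s      # mid-hip -> trunk base
        self.hip_half_width = 0.09 * s
        self.ankle_half_width = 0.10 * s

    # local marker offsets -------------------------------------------------
    def trunk_offsets(self) -> dict:
        """Offsets from the trunk base, in the trunk frame (y ant, z long)."""
        s = self.scale
        return {
            "CLAV": (0.0, 0.06, 0.46 * s), "T2": (0.0, -0.06, 0.46 * s),
            "STRN": (0.0, 0.06, 0.28 * s), "T7": (0.0, -0.06, 0.28 * s),
            "LSHO": (-0.17 * s, 0.0, 0.43 * s), "RSHO": (0.17 * s, 0.0, 0.43 * s),
            "LFHD": (-0.07 * s, 0.09, 0.68 * s), "RFHD": (0.07 * s, 0.09, 0.68 * s),
            "LBHD": (-0.07 * s, -0.07, 0.66 * s), "RBHD": (0.07 * s, -0.07, 0.66 * s),
        }

    def pelvis_offsets(self) -> dict:
        """Offsets from the mid-hip point, in the pelvis frame."""
        s = self.scale
        return {
            "LASI": (-0.11 * s, 0.10 * s, 0.02), "RASI": (0.11 * s, 0.10 * s, 0.02),
            "LPSI": (-0.04 * s, -0.09 * s, 0.03), "RPSI": (0.04 * s, -0.09 * s, 0.03),
            "SJ1": (0.0, -0.12 * s, 0.05), "SJ2": (0.07 * s, -0.17 * s, 0.09),
            "SJ3": (-0.06 * s, -0.16 * s, 0.15),
            "LHIP": (-self.hip_half_width, 0.0, 0.0),
            "RHIP": (self.hip_half_width, 0.0, 0.0),
        }


@dataclass
class MotionScript:
    """Per-trial timing and the scripted values of the three indices.

    Each of ``n_cycles`` identical cycles contains, in order: forward lean
    (trunk 0 -> peak flexion over ``lean_duration_s``), seat-off at
    ``seat_off_offset_s``, maximum ankle dorsiflexion
    ``dorsi_peak_offset_s`` later, extension to stand, a hold, and the
    reverse (sit-down) motion. Peak flexion always precedes seat-off.
    """

    peak_flexion_deg: float = 41.0
    com_velocity_ms: float | None = 0.436
    com_bos_m: float | None = -0.023
    n_cycles: int = 5
    cycle_duration_s: float = 7.5
    start_margin_s: float = 1.0
    end_margin_s: float = 1.0
    lean_duration_s: float = 1.5
    seat_off_offset_s: float = 1.8
    dorsi_peak_offset_s: float = 0.3
    stand_flexion_deg: float = 3.0
    peak_dorsiflexion_deg: float = 15.0

    def __post_init__(self):
        require(self.n_cycles >= 0, "n_cycles must be >= 0")
        require(self.cycle_duration_s > 0, "cycle duration must be positive")
        require(0 < self.lean_duration_s < self.seat_off_offset_s,
                "peak flexion must occur before seat-off")
        require(self.seat_off_offset_s >= 0.5,
                "seat-off must leave room for the unloading ramp")
        require(self.dorsi_peak_offset_s > 0,
                "max dorsiflexion must follow seat-off")
        require(
            self.seat_off_offset_s + self.dorsi_peak_offset_s + 5.0
            <= self.cycle_duration_s + 1e-9,
            "cycle too short for extension + reverse phases",
        )
        require(self.peak_flexion_deg >= 0, "peak flexion must be >= 0")

    @property
    def duration_s(self) -> float:
        return (self.start_margin_s + self.n_cycles * self.cycle_duration_s
                + self.end_margin_s)

    @property
    def cycle_starts(self) -> np.ndarray:
        return self.start_margin_s + np.arange(self.n_cycles) * self.cycle_duration_s

    @property
    def seat_off_times(self) -> np.ndarray:
        return self.cycle_starts + self.seat_off_offset_s

    @property
    def max_dorsi_times(self) -> np.ndarray:
        return self.seat_off_times + self.dorsi_peak_offset_s

    @property
    def support_window(self) -> tuple[float, float]:
        """Onset of the first stand-up to hand release after the fifth."""
        require(self.n_cycles >= 1, "support window needs at least one cycle")
        return (self.start_margin_s,
                self.start_margin_s + self.n_cycles * self.cycle_duration_s - 0.3)

    # joint-angle keyframes ------------------------------------------------
    def _knots(self, values_fn) -> list[tuple[float, float]]:
        knots = [(0.0, values_fn("rest"))]
        D = self.cycle_duration_s
        for c in self.cycle_starts:
            so = self.seat_off_offset_s
            knots += [
                (c + off, values_fn(tag))
                for off, tag in values_fn("schedule")(so, D)
            ]
        knots.append((self.duration_s, values_fn("rest")))
        return knots

    def trunk_knots(self) -> list[tuple[float, float]]:
        peak, stand = self.peak_flexion_deg, min(self.stand_flexion_deg,
                                                 self.peak_flexion_deg)
        D, so, lean = self.cycle_duration_s, self.seat_off_offset_s, self.lean_duration_s
        knots = [(0.0, 0.0)]
        for c in self.cycle_starts:
            knots += [
                (c, 0.0),
                (c + lean, peak),
                (c + so + 0.1, peak),          # brief hold through seat-off
                (c + so + 1.6, stand),
                (c + D - 2.7, stand),
                (c + D - 1.7, 0.8 * peak),     # sit-down lean, shallower
                (c + D - 0.5, 0.0),
            ]
        knots.append((self.duration_s, 0.0))
        return knots

    def dorsi_knots(self) -> list[tuple[float, float]]:
        D, so, lean = self.cycle_duration_s, self.seat_off_offset_s, self.lean_duration_s
        peak = self.peak_dorsiflexion_deg
        knots = [(0.0, 2.0)]
        for c in self.cycle_starts:
            knots += [
                (c + max(lean - 0.3, 0.1), 2.0),
                (c + so + self.dorsi_peak_offset_s, peak),
                (c + so + 1.8, 1.0),
                (c + D - 2.5, 1.0),
                (c + D - 1.3, 2.5),
                (c + D - 0.3, 2.0),
            ]
        knots.append((self.duration_s, 2.0))
        return knots

    def rise_knots(self) -> list[tuple[float, float]]:
        D, so = self.cycle_duration_s, self.seat_off_offset_s
        knots = [(0.0, 0.0)]
        for c in self.cycle_starts:
            knots += [
                (c + so - 0.1, 0.0),
                (c + so + 1.4, 1.0),
                (c + D - 2.5, 1.0),
                (c + D - 0.7, 0.0),
            ]
        knots.append((self.duration_s, 0.0))
        return knots

    def rear_force_knots(self, f_seat: float) -> list[tuple[float, float]]:
        D, so = self.cycle_duration_s, self.seat_off_offset_s
        knots = [(0.0, f_seat)]
        for c in self.cycle_starts:
            knots += [
                (c + so - 0.4, f_seat),
                (c + so, 0.0),          # exactly 0 N at the scripted seat-off
                (c + D - 1.0, 0.0),
                (c + D - 0.7, f_seat),
            ]
        knots.append((self.duration_s, f_seat))
        return knots


# ---------------------------------------------------------------------------
# minimum-jerk interpolation


def minjerk_ramp(t: np.ndarray, knots: list[tuple[float, float]]) -> np.ndarray:
    """Piecewise minimum-jerk interpolation through (time, value) knots.

    Constant before the first and after the last knot; between knots the
    classic quintic smoothstep (zero velocity/acceleration at both ends).
    """
    t = np.asarray(t, dtype=float)
    kt = np.array([k[0] for k in knots])
    kv = np.array([k[1] for k in knots])
    require(np.all(np.diff(kt) > 0), "knot times must be strictly increasing")
    out = np.empty_like(t)
    idx = np.searchsorted(kt, t, side="right") - 1
    idx = np.clip(idx, 0, kt.size - 2)
    u = (t - kt[idx]) / (kt[idx + 1] - kt[idx])
    u = np.clip(u, 0.0, 1.0)
    s = u ** 3 * (10.0 - 15.0 * u + 6.0 * u * u)
    out = kv[idx] + (kv[idx + 1] - kv[idx]) * s
    out[t <= kt[0]] = kv[0]
    out[t >= kt[-1]] = kv[-1]
    return out


def _rotx_apply(angle_rad: np.ndarray, offset) -> np.ndarray:
    """Rotate a constant offset vector about the lab x-axis, per frame."""
    ox, oy, oz = offset
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return np.stack(
        [np.full_like(c, ox), oy * c - oz * s, oy * s + oz * c], axis=1
    )


# ---------------------------------------------------------------------------
# marker forward model


def _pose_markers(
    skeleton: SkeletonModel,
    theta_deg: np.ndarray,
    psi_deg: np.ndarray,
    rise: np.ndarray,
) -> np.ndarray:
    """Marker positions (n, 37, 3) for given trunk flexion, shank
    inclination and rise fraction (0 = seated on the chair, 1 = standing)."""
    sk = skeleton
    s = sk.scale
    n = theta_deg.shape[0]
    theta = np.radians(theta_deg)
    psi = np.radians(psi_deg)
    rho = 0.35 * theta  # pelvis anterior tilt rides along with the trunk

    out: dict[str, np.ndarray] = {}

    # feet: planted, constant
    for side, sx in (("L", -1.0), ("R", 1.0)):
        ax = sx * sk.ankle_half_width
        out[f"{side}ANK"] = np.tile([ax + sx * 0.03 * s, 0.0, sk.ankle_z], (n, 1))
        out[f"{side}HEE"] = np.tile([ax, -0.06 * s, 0.03 * s], (n, 1))
        out[f"{side}TOE"] = np.tile([ax, 0.15 * s, 0.02 * s], (n, 1))

    # shank: rotates forward over the planted foot by psi (dorsiflexion)
    shank_dir = np.stack([np.zeros(n), np.sin(psi), np.cos(psi)], axis=1)
    knee_joints = {}
    for side, sx in (("L", -1.0), ("R", 1.0)):
        aj = np.tile([sx * sk.ankle_half_width, 0.0, sk.ankle_z], (n, 1))
        kj = aj + sk.shank_len * shank_dir
        knee_joints[side] = kj
        out[f"{side}KNE"] = kj + np.array([sx * 0.03 * s, 0.0, 0.0])
        out[f"{side}TIB"] = 0.5 * (aj + kj) + np.array([sx * 0.05 * s, 0.0, 0.0])

    # mid-hip from thigh elevation angle, seated -> standing
    kj_mid = 0.5 * (knee_joints["L"] + knee_joints["R"])
    seat_z = sk.chair_height_m + 0.05 * s
    dz = np.clip((seat_z - kj_mid[:, 2]) / sk.thigh_len, -0.95, 0.95)
    lam_seat = np.arcsin(dz)
    lam_stand = np.radians(80.0)
    lam = lam_seat + rise * (lam_stand - lam_seat)
    mid_hip = kj_mid + sk.thigh_len * np.stack(
        [np.zeros(n), -np.cos(lam), np.sin(lam)], axis=1
    )

    for name, off in skeleton.pelvis_offsets().items():
        out[name] = mid_hip + _rotx_apply(rho, off)

    # trunk base sits on the pelvis; trunk markers rotate by theta about x
    trunk_base = mid_hip + _rotx_apply(rho, (0.0, 0.0, sk.pelvis_up))
    for name, off in skeleton.trunk_offsets().items():
        out[name] = trunk_base + _rotx_apply(theta, off)

    # arms hang near-vertically from the shoulders
    for side, sx in (("L", -1.0), ("R", 1.0)):
        sho = out[f"{side}SHO"]
        out[f"{side}ELB"] = sho + np.array([0.0, 0.03, -0.28 * s])
        out[f"{side}WRA"] = sho + np.array([-sx * 0.015 * s, 0.05, -0.52 * s])
        out[f"{side}WRB"] = sho + np.array([sx * 0.015 * s, 0.06, -0.52 * s])
        hip = out[f"{side}HIP"]
        out[f"{side}THI"] = (
            0.5 * (hip + knee_joints[side]) + np.array([sx * 0.06 * s, 0.02, 0.0])
        )

    return np.stack([out[m] for m in ALL_MARKERS], axis=1)


def _apply_com_targets(
    positions: np.ndarray,
    times: np.ndarray,
    script: MotionScript,
    segments: SegmentSet,
) -> None:
    """Shape the whole-body COM to the scripted COM-BOS and velocity.

    Over a padded window around each [seat-off, max dorsiflexion] span the
    forward COM coordinate is made exactly linear: it passes through
    heel_y + com_bos at seat-off with slope com_velocity. The required
    forward shift is applied rigidly to every segment above the knee
    (translation only: angles, heel positions and ankle geometry are
    unchanged), scaled by the shifted mass fraction. Outside the window the
    shift blends smoothly to zero. In-place.
    """
    if script.com_velocity_ms is None or script.com_bos_m is None:
        return
    names = list(ALL_MARKERS)
    shift_idx = [i for i, m in enumerate(names) if m in _SHIFT_MARKERS]
    kappa = shift_sensitivity(segments, set(_SHIFT_MARKERS))

    base = MarkerTrajectorySet(tuple(names), positions, rate=_rate_of(times))
    com_y = kinematics.whole_body_com(base, segments)[:, 1]
    heel_y = min(positions[0, names.index("LHEE"), 1],
                 positions[0, names.index("RHEE"), 1])

    pad_pre, pad_post, lead, tail = 0.10, 0.10, 0.6, 1.0
    shift = np.zeros_like(times)
    for t_so, t_md in zip(script.seat_off_times, script.max_dorsi_times):
        w0, w1 = t_so - pad_pre, t_md + pad_post
        in_w = (times >= w0) & (times <= w1)
        target = heel_y + script.com_bos_m + script.com_velocity_ms * (
            times[in_w] - t_so
        )
        s_w = (target - com_y[in_w]) / kappa
        shift[in_w] = s_w
        # smooth lead-in and tail-out
        pre = (times >= w0 - lead) & (times < w0)
        u = (times[pre] - (w0 - lead)) / lead
        shift[pre] = s_w[0] * u ** 3 * (10 - 15 * u + 6 * u * u)
        post = (times > w1) & (times <= w1 + tail)
        u = (times[post] - w1) / tail
        shift[post] = s_w[-1] * (1.0 - u ** 3 * (10 - 15 * u + 6 * u * u))
    positions[:, shift_idx, 1] += shift[:, None]


def _rate_of(times: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(times)))


def generate_motion(
    script: MotionScript,
    skeleton: SkeletonModel | None = None,
    rate: float = 100.0,
    rng: np.random.Generator | None = None,
    marker_noise_sd_m: float = 0.0,
    occlusion_threshold_deg: float = 25.0,
    segments: SegmentSet | None = None,
) -> MarkerTrajectorySet:
    """Forward-kinematic realization of a motion script.

    Returns 37 marker trajectories at ``rate``. The ASIS markers are
    blanked (missing) whenever trunk flexion exceeds the occlusion
    threshold, emulating the torso obscuring them during forward bending.
    The deepest trunk flexion of the clean motion equals the scripted peak
    to well within 0.1 degrees.
    """
    skeleton = skeleton or SkeletonModel()
    segments = segments or default_segments()
    n = int(round(script.duration_s * rate)) + 1
    t = np.arange(n) / rate
    theta = minjerk_ramp(t, script.trunk_knots()) if script.n_cycles else np.zeros(n)
    psi = minjerk_ramp(t, script.dorsi_knots()) if script.n_cycles else np.full(n, 2.0)
    rise = minjerk_ramp(t, script.rise_knots()) if script.n_cycles else np.zeros(n)

    pos = _pose_markers(skeleton, theta, psi, rise)
    if script.n_cycles:
        _apply_com_targets(pos, t, script, segments)

    if marker_noise_sd_m > 0:
        rng = rng or np.random.default_rng(0)
        pos = pos + rng.normal(0.0, marker_noise_sd_m, size=pos.shape)

    occluded = theta > occlusion_threshold_deg
    if occluded.any():
        names = list(ALL_MARKERS)
        for m in ("LASI", "RASI"):
            pos[occluded, names.index(m), :] = np.nan

    return MarkerTrajectorySet(ALL_MARKERS, pos, rate)


def generate_static(
    skeleton: SkeletonModel | None = None,
    rate: float = 100.0,
    duration_s: float = 0.5,
    rng: np.random.Generator | None = None,
    marker_noise_sd_m: float = 0.0,
) -> MarkerTrajectorySet:
    """Static standing calibration capture with all 37 markers visible."""
    skeleton = skeleton or SkeletonModel()
    n = int(round(duration_s * rate)) + 1
    zero = np.zeros(n)
    pos = _pose_markers(skeleton, zero, np.full(n, 2.0), np.ones(n))
    if marker_noise_sd_m > 0:
        rng = rng or np.random.default_rng(0)
        pos = pos + rng.normal(0.0, marker_noise_sd_m, size=pos.shape)
    return MarkerTrajectorySet(ALL_MARKERS, pos, rate)


# ---------------------------------------------------------------------------
# ground reaction forces


def generate_grf(
    script: MotionScript,
    body_mass_kg: float = 60.0,
    rate: float = 1000.0,
    rng: np.random.Generator | None = None,
    noise_sd_n: float = 0.0,
    seat_fraction: float = 0.7,
) -> ForcePlateSeries:
    """Six-plate force series: chair on the two rear plates.

    The summed rear-plate vertical force is constant while seated, decays
    linearly to exactly 0 N at each scripted seat-off, stays 0 while
    standing and ramps back at sit-down contact; the foot plates carry the
    quasi-static complement. A script without stand-up cycles produces a
    rear force that never unloads.
    """
    require(body_mass_kg > 0, "body mass must be positive")
    n = int(round(script.duration_s * rate)) + 1
    t = np.arange(n) / rate
    weight = body_mass_kg * G_ACCEL
    f_seat = seat_fraction * weight

    if script.n_cycles:
        knots = script.rear_force_knots(f_seat)
        kt = np.array([k[0] for k in knots])
        kv = np.array([k[1] for k in knots])
        rear = np.interp(t, kt, kv)
    else:
        rear = np.full(n, f_seat)
    front = weight - rear

    forces = np.zeros((n, 6, 3))
    forces[:, 2, 2] = 0.5 * front          # fp3, fp4: feet
    forces[:, 3, 2] = 0.5 * front
    forces[:, 4, 2] = 0.52 * rear          # fp5, fp6: chair
    forces[:, 5, 2] = 0.48 * rear
    if noise_sd_n > 0:
        rng = rng or np.random.default_rng(0)
        forces = forces + rng.normal(0.0, noise_sd_n, size=forces.shape)
    return ForcePlateSeries(
        plate_ids=tuple(f"fp{i}" for i in range(1, 7)),
        forces=forces,
        rate=rate,
        rear_plates=("fp5", "fp6"),
    )


# ---------------------------------------------------------------------------
# gaze


def generate_gaze(
    profile: dict,
    layout: "gm.AOILayout",
    window_s: tuple[float, float],
    duration_s: float,
    rate: float = 50.0,
    rng: np.random.Generator | None = None,
    jitter_sd_m: float = 0.0005,
) -> GazeStream:
    """Gaze stream realizing per-AOI dwell fractions and fixation counts.

    ``profile`` maps AOI name -> (dwell_pct, n_fixations) for this trial.
    Fixation episodes (low-velocity clusters anchored inside the AOI band
    at their midpoint frame) alternate with high-velocity saccade/wander
    samples; all fixations are scheduled inside the support window, and
    each lasts at least 80 ms so the I-VT filter recovers it.
    """
    rng = rng or np.random.default_rng(0)
    total = sum(d for d, _ in profile.values())
    if total > 100.0 + 1e-9:
        raise ValidationError(f"dwell fractions sum to {total:.1f}% > 100%")

    dt_ms = 1000.0 / rate
    n = int(round(duration_s * rate)) + 1
    ts = np.arange(n) * dt_ms
    w0, w1 = window_s
    i0 = int(np.ceil(w0 * rate))
    i1 = int(np.floor(w1 * rate))
    s_window = i1 - i0 + 1
    require(s_window > 10, "support window too short for gaze scheduling")

    # integer sample budgets per AOI
    budgets: list[tuple[str, int, int]] = []
    for aoi, (dwell_pct, n_fix) in profile.items():
        s_a = int(round(dwell_pct / 100.0 * s_window))
        if s_a < _MIN_FIX_SAMPLES:
            continue
        n_a = int(np.clip(n_fix, 1, s_a // _MIN_FIX_SAMPLES))
        budgets.append((aoi, s_a, n_a))

    # rescale if fixations + minimal gaps do not fit; the first and last
    # gap may be empty (out-of-window wander already separates fixations)
    total_fix = sum(s for _, s, _ in budgets)
    n_blocks = sum(na for _, _, na in budgets)
    min_gaps = 2 * max(n_blocks - 1, 0)
    if total_fix + min_gaps > s_window:
        f = max(s_window - min_gaps, _MIN_FIX_SAMPLES) / total_fix
        budgets = [
            (a, max(int(s * f), _MIN_FIX_SAMPLES),
             min(na, max(int(s * f), _MIN_FIX_SAMPLES) // _MIN_FIX_SAMPLES))
            for a, s, na in budgets
        ]
        total_fix = sum(s for _, s, _ in budgets)
        n_blocks = sum(na for _, _, na in budgets)

    # split each AOI budget into fixation blocks of >= 4 samples
    blocks: list[tuple[str, int]] = []
    for aoi, s_a, n_a in budgets:
        base, rem = divmod(s_a, n_a)
        blocks += [(aoi, base + 1)] * rem + [(aoi, base)] * (n_a - rem)
    order = rng.permutation(len(blocks))
    blocks = [blocks[k] for k in order]

    # distribute gap samples (interior gaps >= 2 samples, edge gaps >= 0)
    n_gaps = len(blocks) + 1
    base_gaps = np.full(n_gaps, 2)
    base_gaps[0] = base_gaps[-1] = 0
    spare = s_window - sum(b[1] for b in blocks) - int(base_gaps.sum())
    extra = rng.multinomial(max(spare, 0), np.full(n_gaps, 1.0 / n_gaps))
    gaps = base_gaps + extra

    points = np.zeros((n, 2))
    _fill_wander(points, 0, n, rng)

    cursor = i0
    for b, (aoi, length) in enumerate(blocks):
        cursor += int(gaps[b])
        mid_t = ts[cursor + length // 2] / 1000.0
        anchor = _band_anchor(layout, aoi, mid_t)
        pts = anchor + rng.normal(0.0, jitter_sd_m, size=(length, 2))
        points[cursor:cursor + length] = pts
        cursor += length

    return GazeStream(ts, points, np.ones(n, dtype=bool), rate=rate)


def _fill_wander(points: np.ndarray, start: int, stop: int, rng) -> None:
    """High-velocity scanning: every inter-sample step is a large jump."""
    k = stop - start
    if k <= 0:
        return
    sign = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    points[start:stop, 0] = sign * 0.35 + rng.normal(0, 0.05, k)
    points[start:stop, 1] = 0.9 + sign * 0.35 + rng.normal(0, 0.05, k)


def _band_anchor(layout: "gm.AOILayout", aoi: str, t_s: float) -> np.ndarray:
    """A point safely inside the AOI band at time t."""
    rate = 1.0 / float(np.median(np.diff(layout.times_s)))
    idx = int(np.clip(round((t_s - layout.times_s[0]) * rate),
                      0, layout.times_s.size - 1))
    lo, hi = (b[idx] for b in layout.bounds[aoi])
    if aoi == "head":
        v = lo + 0.10
    elif aoi == "foot":
        v = hi - 0.05
    else:
        v = 0.5 * (lo + hi)
    return np.array([0.0, v])


# ---------------------------------------------------------------------------
# cohort assembly


def _gamma_quantile(u: float, mean: float, sd: float) -> float:
    """Inverse-CDF of a gamma with exactly the requested mean and sd."""
    if mean <= 0:
        return 0.0
    if sd <= 0:
        return mean
    k = (mean / sd) ** 2
    return float(sps.gamma.ppf(u, k, scale=sd * sd / mean))


def _draw_participant(rng, params: GroupParams, bet: float) -> dict:
    """Participant-level draws (the between-participant variance share).

    Dwell percentage and fixation count per AOI share one uniform quantile
    (comonotone draws): both marginal means/sds are preserved exactly and
    looking longer co-occurs with fixating more, so the realized counts are
    almost never clipped by the minimum fixation duration.
    """
    sb = np.sqrt(bet)
    draws = {
        "trunk": rng.normal(params.trunk_angle_mean_deg,
                            params.trunk_angle_sd_deg * sb),
        "com_bos": rng.normal(params.com_bos_mean_m, params.com_bos_sd_m * sb),
        "com_vel": rng.normal(params.com_velocity_mean_ms,
                              params.com_velocity_sd_ms * sb),
        "gaze": {},
    }
    for aoi, p in params.aoi_gaze_profile.items():
        u = rng.uniform()
        draws["gaze"][aoi] = (
            _gamma_quantile(u, p.dwell_pct_mean, p.dwell_pct_sd * sb),
            _gamma_quantile(u, p.n_fix_mean, p.n_fix_sd * sb),
        )
    return draws


def _draw_trial(rng, part: dict, params: GroupParams, wit: float) -> dict:
    """Trial-level draws around the participant's values (within share)."""
    sw = np.sqrt(wit)
    trial = {
        "trunk": max(rng.normal(part["trunk"], params.trunk_angle_sd_deg * sw), 1.0),
        "com_bos": rng.normal(part["com_bos"], params.com_bos_sd_m * sw),
        "com_vel": max(rng.normal(part["com_vel"],
                                  params.com_velocity_sd_ms * sw), 0.05),
        "gaze": {},
    }
    for aoi, p in params.aoi_gaze_profile.items():
        d_p, n_p = part["gaze"][aoi]
        u = rng.uniform()
        d = _gamma_quantile(u, d_p, p.dwell_pct_sd * sw)
        c = _gamma_quantile(u, n_p, p.n_fix_sd * sw)
        trial["gaze"][aoi] = (d, int(round(c)))
    return trial


def iter_trials(config: CohortConfig):
    """Lazily generate every trial of a cohort (memory-friendly).

    Per-participant parameters are drawn once from the group distribution
    and held fixed across that participant's trials; trial-level draws add
    the within-participant share of the variance. All streams share one
    trial clock starting at 0.
    """
    skeleton = SkeletonModel(config.stature_m, config.body_mass_kg)
    bet = config.between_participant_frac
    for gi, (group, n_part) in enumerate(config.groups()):
        params = config.group_params[group]
        for pi in range(n_part):
            rng_p = split_seed(config.seed, "participant", gi, pi)
            part = _draw_participant(rng_p, params, bet)
            static = generate_static(
                skeleton, rng=rng_p, marker_noise_sd_m=config.marker_noise_sd_m
            )
            pid = f"{'E' if group == 'expert' else 'N'}{pi + 1:02d}"
            for ti in range(config.trials_per_participant):
                yield _make_trial(
                    config, skeleton, group, gi, pid, pi, ti, part, params,
                    static,
                )


def _make_trial(config, skeleton, group, gi, pid, pi, ti, part, params, static):
    rng_t = split_seed(config.seed, "trial", gi, pi, ti)
    draws = _draw_trial(rng_t, part, params, 1.0 - config.between_participant_frac)
    script = MotionScript(
        peak_flexion_deg=draws["trunk"],
        com_velocity_ms=draws["com_vel"],
        com_bos_m=draws["com_bos"],
    )
    markers = generate_motion(
        script, skeleton,
        rng=split_seed(config.seed, "markers", gi, pi, ti),
        marker_noise_sd_m=config.marker_noise_sd_m,
    )
    grf = generate_grf(
        script, config.body_mass_kg,
        rng=split_seed(config.seed, "grf", gi, pi, ti),
        noise_sd_n=config.grf_noise_sd_n,
    )
    # layout for gaze generation comes from the clean motion
    clean = generate_motion(script, skeleton, marker_noise_sd_m=0.0)
    layout = gm.build_aoi_layout(_restore_asis(clean, skeleton))
    gaze = generate_gaze(
        draws["gaze"], layout, script.support_window, script.duration_s,
        rng=split_seed(config.seed, "gaze", gi, pi, ti),
        jitter_sd_m=config.gaze_jitter_sd_m,
    )
    meta = {
        "group": group,
        "participant_id": pid,
        "trial_id": f"{pid}T{ti + 1}",
        "seed": config.seed,
        "n_cycles": script.n_cycles,
        "support_window_s": [float(x) for x in script.support_window],
        "hand_release_s": float(script.support_window[1]),
        "body_mass_kg": config.body_mass_kg,
        "stature_m": config.stature_m,
        "units": "m",
        "scripted": {
            "peak_flexion_deg": script.peak_flexion_deg,
            "com_velocity_ms": script.com_velocity_ms,
            "com_bos_m": script.com_bos_m,
            "seat_off_times_s": [float(x) for x in script.seat_off_times],
            "max_dorsi_times_s": [float(x) for x in script.max_dorsi_times],
        },
    }
    return TrialDataset(markers, grf, gaze, static, meta)


def _restore_asis(
    markers: MarkerTrajectorySet, skeleton: SkeletonModel | None = None
) -> MarkerTrajectorySet:
    """Fill the ASIS occlusion gaps of a clean motion via the jig: the AOI
    layout needs the pelvis height on every frame."""
    pose = kinematics.calibrate_virtual_asis(generate_static(skeleton))
    filled, _ = kinematics.reconstruct_asis(markers, pose)
    return filled


def generate_cohort(config: CohortConfig) -> list[TrialDataset]:
    """All trials of a cohort as a list: (n_expert + n_novice) x trials."""
    return list(iter_trials(config))
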