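"""Fixation detection (I-VT), AOI geometry and the four gaze metrics.

Gaze samples live in a body-anchored 2D analysis plane whose vertical
coordinate is lab height; the six areas of interest (head, neck, upper
trunk, hip, knee, foot) are height bands whose boundaries follow the
collaborator's marker landmarks frame by frame:

    head  [chin, inf)          chin = head-marker centroid - chin offset
    neck  [acromion, chin)
    trunk [mid acromion-hip, acromion)     upper 50% of that span
    hip   [mid-thigh, mid acromion-hip)
    knee  [mid-shank, mid-thigh)
    foot  (-inf, lateral malleolus)

Bands are half-open [lower, upper): a point exactly on a shared boundary
belongs to the upper band. A fixation's AOI is decided by its centroid at
its midpoint frame.

All four metrics are computed over the support period: from the onset of
the collaborator's first stand-up motion to the scripted hand release
after the fifth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AOI_NAMES,
    Fixation,
    GazeStream,
    MarkerTrajectorySet,
    TrialDataset,
    ValidationError,
)
from . import kinematics

DEFAULT_VELOCITY_THRESHOLD_DPS = 30.0
DEFAULT_MIN_FIXATION_MS = 60.0
DEFAULT_VIEWING_DISTANCE_M = 1.0
DEFAULT_CHIN_OFFSET_M = 0.12
DEFAULT_ONSET_ANGVEL_DPS = 5.0


def detect_fixations(
    stream: GazeStream,
    velocity_threshold_dps: float = DEFAULT_VELOCITY_THRESHOLD_DPS,
    min_fixation_ms: float = DEFAULT_MIN_FIXATION_MS,
    viewing_distance_m: float = DEFAULT_VIEWING_DISTANCE_M,
) -> list[Fixation]:
    """I-VT classification of a gaze stream into fixations.

    Inter-sample angular velocity (plane displacement converted to visual
    angle at the configured viewing distance) is compared against the
    threshold; a fixation is a maximal run of consecutive below-threshold
    steps between valid samples, spanning both endpoint samples. Duration
    is sample count times the sample period, so a 500 ms dwell at 50 Hz is
    recovered as 500 ms. Fixations shorter than ``min_fixation_ms`` are
    discarded. A stream shorter than the minimum yields an empty list.
    """
    n = stream.n_samples
    if n < 2:
        return []
    t = stream.timestamps_ms
    p = stream.points
    dt_s = np.diff(t) / 1000.0
    disp = np.linalg.norm(np.diff(p, axis=0), axis=1)
    ang_deg = np.degrees(2.0 * np.arctan2(disp, 2.0 * viewing_distance_m))
    vel = ang_deg / dt_s
    slow = (vel < velocity_threshold_dps) & stream.validity[:-1] & stream.validity[1:]

    dt_ms = float(np.median(np.diff(t)))
    fixations: list[Fixation] = []
    i = 0
    while i < n - 1:
        if not slow[i]:
            i += 1
            continue
        j = i
        while j < n - 1 and slow[j]:
            j += 1
        # steps i..j-1 are slow -> samples i..j belong to the fixation
        n_samples = j - i + 1
        duration = n_samples * dt_ms
        if duration >= min_fixation_ms:
            centroid = p[i:j + 1].mean(axis=0)
            fixations.append(
                Fixation(float(t[i]), float(duration),
                         (float(centroid[0]), float(centroid[1])))
            )
        i = j
    return fixations


# ---------------------------------------------------------------------------
# AOI geometry


@dataclass
class AOILayout:
    """Per-frame height boundaries of the six AOI bands.

    ``bounds`` maps AOI name -> (lower, upper) arrays over marker frames;
    infinite bounds are allowed at the extremes. Frames with an
    unresolvable landmark are flagged and skipped by the metrics.
    """

    times_s: np.ndarray
    bounds: dict
    valid: np.ndarray

    def label_points(self, v: np.ndarray, t_s: np.ndarray) -> np.ndarray:
        """AOI name per point (height v at time t), '' if outside all bands.

        Points are matched to the nearest marker frame. Bands are
        [lower, upper): a boundary point belongs to the band whose lower
        bound it equals (i.e. the upper band).
        """
        v = np.atleast_1d(np.asarray(v, dtype=float))
        t_s = np.atleast_1d(np.asarray(t_s, dtype=float))
        rate = 1.0 / np.median(np.diff(self.times_s))
        idx = np.clip(
            np.round((t_s - self.times_s[0]) * rate).astype(int),
            0, self.times_s.size - 1,
        )
        labels = np.full(v.shape, "", dtype=object)
        frame_ok = self.valid[idx]
        for name in AOI_NAMES:
            lo, hi = self.bounds[name]
            inside = (v >= lo[idx]) & (v < hi[idx]) & frame_ok
            labels[inside & (labels == "")] = name
        return labels


def build_aoi_layout(
    markers: MarkerTrajectorySet,
    chin_offset_m: float = DEFAULT_CHIN_OFFSET_M,
) -> AOILayout:
    """Derive the six AOI height bands from marker landmarks, per frame.

    Requires head, shoulder, pelvis, knee and ankle landmarks; the chin is
    not in the marker set and is estimated a fixed offset below the
    head-marker centroid. Frames with any required landmark missing are
    flagged invalid.
    """
    def centroid(names):
        return np.nanmean(
            np.stack([markers.get(m) for m in names], axis=0), axis=0
        )[:, 2]

    head = centroid(("LFHD", "RFHD", "LBHD", "RBHD"))
    acro = centroid(("LSHO", "RSHO"))
    hip = centroid(("LASI", "RASI", "LPSI", "RPSI"))
    knee = centroid(("LKNE", "RKNE"))
    ankle = centroid(("LANK", "RANK"))

    chin = head - chin_offset_m
    t50 = hip + 0.5 * (acro - hip)
    midthigh = 0.5 * (hip + knee)
    midshank = 0.5 * (knee + ankle)

    n = markers.n_frames
    inf = np.full(n, np.inf)
    bounds = {
        "head": (chin, inf),
        "neck": (acro, chin),
        "trunk": (t50, acro),
        "hip": (midthigh, t50),
        "knee": (midshank, midthigh),
        "foot": (-inf, ankle),
    }
    valid = np.ones(n, dtype=bool)
    for lo, hi in bounds.values():
        valid &= np.isfinite(lo) | np.isneginf(lo)
        valid &= np.isfinite(hi) | np.isposinf(hi)
    return AOILayout(markers.times, bounds, valid)


def assign_aoi(fixations: list[Fixation], layout: AOILayout) -> list[str]:
    """AOI label per fixation: centroid membership at the midpoint frame."""
    if not fixations:
        return []
    v = np.array([f.centroid[1] for f in fixations])
    t = np.array([f.midpoint_ms for f in fixations]) / 1000.0
    return list(layout.label_points(v, t))


# ---------------------------------------------------------------------------
# support period


def support_period(
    trial: TrialDataset,
    markers: MarkerTrajectorySet | None = None,
    onset_angvel_dps: float = DEFAULT_ONSET_ANGVEL_DPS,
) -> tuple[float, float]:
    """Analysis window: first stand-up onset to hand release.

    The onset is the first frame where trunk angular velocity exceeds the
    threshold; the release time is scripted metadata (``hand_release_s``),
    as it is not observable from the collaborator's markers. Trials whose
    metadata script the full window (``support_window_s``) return it
    directly.
    """
    if "support_window_s" in trial.meta:
        w0, w1 = (float(x) for x in trial.meta["support_window_s"])
        _check_window(trial, w0, w1)
        return w0, w1
    markers = markers if markers is not None else trial.markers
    angle = kinematics.trunk_angle(markers)
    vel = np.abs(np.gradient(angle, 1.0 / markers.rate))
    above = np.flatnonzero(vel > onset_angvel_dps)
    if above.size == 0:
        raise ValidationError("no stand-up onset: trunk never moves")
    w0 = float(markers.times[above[0]])
    if "hand_release_s" not in trial.meta:
        raise ValidationError("trial metadata lacks hand_release_s")
    w1 = float(trial.meta["hand_release_s"])
    _check_window(trial, w0, w1)
    return w0, w1


def _check_window(trial: TrialDataset, w0: float, w1: float) -> None:
    t = trial.gaze.timestamps_ms / 1000.0
    if w1 <= w0:
        raise ValidationError("support window end must follow its start")
    if w0 < t[0] - 1e-9 or w1 > t[-1] + 1e-9:
        raise ValidationError(
            f"support window [{w0}, {w1}] s outside gaze recording "
            f"[{t[0]:.3f}, {t[-1]:.3f}] s"
        )


# ---------------------------------------------------------------------------
# the four AOI metrics


def _clip_to_window(fixations, window_s):
    """Fixations overlapping the window, durations clipped to it."""
    w0, w1 = (1000.0 * w for w in window_s)
    out = []
    for f in fixations:
        a = max(f.start_ms, w0)
        b = min(f.end_ms, w1)
        if b > a:
            out.append(Fixation(a, b - a, f.centroid))
    return out


def total_duration_pct(
    fixations: list[Fixation], layout: AOILayout, window_s: tuple[float, float]
) -> dict:
    """Total fixation time per AOI as % of the support period."""
    w_ms = 1000.0 * (window_s[1] - window_s[0])
    clipped = _clip_to_window(fixations, window_s)
    labels = assign_aoi(clipped, layout)
    out = {a: 0.0 for a in AOI_NAMES}
    for f, lab in zip(clipped, labels):
        if lab:
            out[lab] += f.duration_ms
    return {a: 100.0 * v / w_ms for a, v in out.items()}


def n_fixations(
    fixations: list[Fixation], layout: AOILayout, window_s: tuple[float, float]
) -> dict:
    """Number of fixations per AOI within the support period."""
    clipped = _clip_to_window(fixations, window_s)
    labels = assign_aoi(clipped, layout)
    out = {a: 0 for a in AOI_NAMES}
    for lab in labels:
        if lab:
            out[lab] += 1
    return out


def _visits(labels: list[str], durations: list[float]) -> dict:
    """Visit durations per AOI: consecutive same-AOI fixations merge."""
    out: dict = {a: [] for a in AOI_NAMES}
    prev = None
    for lab, dur in zip(labels, durations):
        if lab and lab == prev:
            out[lab][-1] += dur
        elif lab:
            out[lab].append(dur)
        prev = lab
    return out


def mean_fixation_per_visit(
    fixations: list[Fixation], layout: AOILayout, window_s: tuple[float, float]
) -> dict:
    """Mean summed fixation time (ms) per visit to each AOI.

    A visit is a maximal run of consecutive fixations inside one AOI,
    ended by a fixation outside it; its duration is the sum of its
    fixations. AOIs never visited report NaN (metric absent).
    """
    clipped = _clip_to_window(fixations, window_s)
    labels = assign_aoi(clipped, layout)
    visits = _visits(labels, [f.duration_ms for f in clipped])
    return {
        a: (float(np.mean(v)) if v else float("nan")) for a, v in visits.items()
    }


def latency_first_fixation(
    fixations: list[Fixation], layout: AOILayout, window_s: tuple[float, float]
) -> dict:
    """Time (ms) from window start to the first fixation on each AOI.

    NaN for AOIs never fixated (excluded from group means downstream).
    """
    clipped = _clip_to_window(fixations, window_s)
    labels = assign_aoi(clipped, layout)
    w0_ms = 1000.0 * window_s[0]
    out = {a: float("nan") for a in AOI_NAMES}
    for f, lab in zip(clipped, labels):
        if lab and np.isnan(out[lab]):
            out[lab] = f.start_ms - w0_ms
    return out


def trial_gaze_metrics(
    trial: TrialDataset,
    markers: MarkerTrajectorySet | None = None,
    velocity_threshold_dps: float = DEFAULT_VELOCITY_THRESHOLD_DPS,
    min_fixation_ms: float = DEFAULT_MIN_FIXATION_MS,
    chin_offset_m: float = DEFAULT_CHIN_OFFSET_M,
) -> pd.DataFrame:
    """All four AOI metrics for one trial: one row per AOI."""
    markers = markers if markers is not None else trial.markers
    fixations = detect_fixations(
        trial.gaze, velocity_threshold_dps, min_fixation_ms
    )
    layout = build_aoi_layout(markers, chin_offset_m)
    window = support_period(trial, markers)
    dur = total_duration_pct(fixations, layout, window)
    cnt = n_fixations(fixations, layout, window)
    visit = mean_fixation_per_visit(fixations, layout, window)
    lat = latency_first_fixation(fixations, layout, window)
    rows = [
        {
            "participant": trial.participant_id,
            "group": trial.group,
            "trial": trial.trial_id,
            "aoi": a,
            "total_duration_pct": dur[a],
            "n_fixations": cnt[a],
            "mean_fixation_per_visit_ms": visit[a],
            "latency_first_fixation_ms": lat[a],
        }
        for a in AOI_NAMES
    ]
    return pd.DataFrame(rows)
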