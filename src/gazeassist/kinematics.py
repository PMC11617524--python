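"""Rigid-body kinematics: virtual ASIS, whole-body COM, angles, events.

The forward direction is +y, up is +z. Trunk flexion is the rotation of
the trunk segment about the lab x-axis (X-Y-Z Cardan decomposition),
positive for anterior lean; ankle dorsiflexion is the forward inclination
of the shank over the foot, positive forward.

Seat-off is the instant the summed vertical force on the two plates under
the chair reaches 0 N. On noisy data the detector finds the first
epsilon-crossing sustained for a debounce window; the index pipeline
refines that crossing by extrapolating the unloading ramp to 0 N, which
recovers the literal 0 N definition without the early bias of a positive
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .anthropometry import SegmentSet, default_segments
from .core import (
    ForcePlateSeries,
    MarkerTrajectorySet,
    ValidationError,
)

DEFAULT_SEAT_OFF_EPSILON_N = 5.0
DEFAULT_DEBOUNCE_S = 0.05


class EventDetectionError(RuntimeError):
    """Raised when an expected movement event cannot be found."""


# ---------------------------------------------------------------------------
# virtual ASIS reconstruction


@dataclass
class CalibrationPose:
    """Jig -> ASIS offset vectors in the jig's local orthonormal frame."""

    offset_lasi: np.ndarray
    offset_rasi: np.ndarray

    def __post_init__(self):
        self.offset_lasi = np.asarray(self.offset_lasi, dtype=float)
        self.offset_rasi = np.asarray(self.offset_rasi, dtype=float)
        if not (np.isfinite(self.offset_lasi).all() and
                np.isfinite(self.offset_rasi).all()):
            raise ValidationError("calibration offsets must be finite")


def jig_frames(sj1: np.ndarray, sj2: np.ndarray, sj3: np.ndarray):
    """Orthonormal local frame of the sacral jig, per frame.

    Returns (origin (n,3), R (n,3,3)) with R columns = local axes in lab
    coordinates. Raises if the three jig markers are collinear.
    """
    sj1, sj2, sj3 = (np.atleast_2d(np.asarray(p, dtype=float)) for p in (sj1, sj2, sj3))
    u = sj2 - sj1
    v = sj3 - sj1
    nrm = np.cross(u, v)
    n_len = np.linalg.norm(nrm, axis=1)
    u_len = np.linalg.norm(u, axis=1)
    ok = np.isfinite(n_len) & (u_len > 0)
    if np.any(n_len[ok] < 1e-9 * np.maximum(u_len[ok], 1e-12)):
        raise ValidationError("jig markers are collinear; cannot build local frame")
    with np.errstate(invalid="ignore", divide="ignore"):
        x = u / u_len[:, None]
        z = nrm / n_len[:, None]
        y = np.cross(z, x)
    R = np.stack([x, y, z], axis=2)
    return sj1, R


def calibrate_virtual_asis(static: MarkerTrajectorySet) -> CalibrationPose:
    """Measure jig -> ASIS offsets on a static standing capture.

    All frames with the jig and both ASIS visible contribute; offsets are
    averaged in the jig's local frame, so they are invariant to any rigid
    motion of the subject during the capture.
    """
    needed = ("SJ1", "SJ2", "SJ3", "LASI", "RASI")
    cols = {m: static.get(m) for m in needed}
    valid = np.ones(static.n_frames, dtype=bool)
    for m in needed:
        valid &= ~np.isnan(cols[m]).any(axis=1)
    if not valid.any():
        raise ValidationError(
            "static capture has no frame with jig and both ASIS visible"
        )
    origin, R = jig_frames(
        cols["SJ1"][valid], cols["SJ2"][valid], cols["SJ3"][valid]
    )
    # local = R^T (p - origin)
    def local(p):
        d = p[valid] - origin
        return np.einsum("nij,nj->ni", np.transpose(R, (0, 2, 1)), d).mean(axis=0)

    return CalibrationPose(local(cols["LASI"]), local(cols["RASI"]))


def reconstruct_asis(
    markers: MarkerTrajectorySet, pose: CalibrationPose
) -> tuple[MarkerTrajectorySet, dict]:
    """Fill occluded ASIS samples from the jig and calibration offsets.

    Frames where the real ASIS is visible keep the measurement; the
    discrepancy between measured and virtual positions there is returned
    as a quality metric. Frames with the jig occluded are flagged
    unrecoverable in the report.
    """
    out = markers.copy()
    sj = [markers.get(m) for m in ("SJ1", "SJ2", "SJ3")]
    jig_ok = ~np.isnan(np.concatenate(sj, axis=1)).any(axis=1)
    origin = np.full((markers.n_frames, 3), np.nan)
    R = np.full((markers.n_frames, 3, 3), np.nan)
    if jig_ok.any():
        o, r = jig_frames(sj[0][jig_ok], sj[1][jig_ok], sj[2][jig_ok])
        origin[jig_ok] = o
        R[jig_ok] = r
    report: dict = {"unrecoverable_frames": int((~jig_ok).sum())}
    for name, offset in (("LASI", pose.offset_lasi), ("RASI", pose.offset_rasi)):
        meas = out.get(name)
        virtual = origin + np.einsum("nij,j->ni", R, offset)
        missing = np.isnan(meas).any(axis=1)
        fill = missing & jig_ok
        meas[fill] = virtual[fill]
        seen = ~missing & jig_ok
        if seen.any():
            report[f"{name}_rms_discrepancy_m"] = float(
                np.sqrt(np.mean(np.sum((meas[seen] - virtual[seen]) ** 2, axis=1)))
            )
        report[f"{name}_filled"] = int(fill.sum())
    return out, report


# ---------------------------------------------------------------------------
# whole-body COM and angles


def _landmark(markers: MarkerTrajectorySet, names: tuple[str, ...],
              segment: str) -> np.ndarray:
    pts = np.stack([markers.get(m) for m in names], axis=0)
    out = pts.mean(axis=0)
    if np.isnan(out).any():
        bad = [m for m in names if np.isnan(markers.get(m)).any()]
        raise ValidationError(
            f"segment {segment!r}: unresolvable landmark(s) {bad} "
            "(missing samples; reconstruct/interpolate first)"
        )
    return out


def whole_body_com(
    markers: MarkerTrajectorySet, segments: SegmentSet | None = None
) -> np.ndarray:
    """Mass-weighted whole-body COM trajectory, shape (n_frames, 3).

    COM = sum_i massfrac_i * segCOM_i with each segment COM interpolated
    between its proximal and distal landmark centroids.
    """
    segments = segments or default_segments()
    com = np.zeros((markers.n_frames, 3))
    for seg in segments:
        p = _landmark(markers, seg.proximal, seg.name)
        d = _landmark(markers, seg.distal, seg.name)
        com += seg.mass_fraction * (p + seg.com_fraction * (d - p))
    return com


def trunk_rotation(markers: MarkerTrajectorySet) -> np.ndarray:
    """Trunk segment rotation matrices relative to the lab, (n,3,3).

    The trunk triad is built from the jugular-notch/xiphoid (CLAV, STRN)
    and T2/T7 spinous markers: longitudinal axis up the spine midline,
    anterior axis toward the chest wall.
    """
    clav, strn, t2, t7 = (markers.get(m) for m in ("CLAV", "STRN", "T2", "T7"))
    upper = 0.5 * (clav + t2)
    lower = 0.5 * (strn + t7)
    z = upper - lower
    z = z / np.linalg.norm(z, axis=1, keepdims=True)
    ant = 0.5 * (clav + strn) - 0.5 * (t2 + t7)
    ant = ant - np.sum(ant * z, axis=1, keepdims=True) * z
    y = ant / np.linalg.norm(ant, axis=1, keepdims=True)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=2)


def trunk_angle(markers: MarkerTrajectorySet) -> np.ndarray:
    """Trunk flexion angle in degrees, per frame; anterior lean positive.

    The x component of the X-Y-Z Cardan decomposition of the trunk
    rotation relative to the lab frame.
    """
    R = trunk_rotation(markers)
    ok = np.isfinite(R).all(axis=(1, 2))
    ang = np.full(R.shape[0], np.nan)
    if ok.any():
        ang[ok] = Rotation.from_matrix(R[ok]).as_euler("XYZ", degrees=True)[:, 0]
    return ang


def ankle_dorsiflexion(markers: MarkerTrajectorySet) -> np.ndarray:
    """Mean L/R forward shank inclination over the foot, degrees.

    Positive = dorsiflexion (shank rotated forward about x over a planted
    foot), matching the positive-forward sign convention.
    """
    angles = []
    for side in "LR":
        v = markers.get(f"{side}KNE") - markers.get(f"{side}ANK")
        angles.append(np.degrees(np.arctan2(v[:, 1], v[:, 2])))
    return np.nanmean(np.stack(angles), axis=0)


# ---------------------------------------------------------------------------
# events


def detect_seat_off(
    grf: ForcePlateSeries,
    epsilon_n: float = DEFAULT_SEAT_OFF_EPSILON_N,
    debounce_s: float = DEFAULT_DEBOUNCE_S,
    expected_cycles: int | None = None,
    refine: str | None = None,
) -> np.ndarray:
    """Seat-off times: rear-plate vertical force unloading to 0 N.

    An event is the first time the summed rear-plate vertical force falls
    to ``epsilon_n`` and stays below it for ``debounce_s``. The returned
    time is the linearly interpolated epsilon-crossing; with
    ``refine='extrapolate'`` the unloading ramp preceding the crossing is
    regressed and extrapolated to 0 N, removing the epsilon-induced early
    bias.
    """
    f = grf.rear_vertical_total()
    t = grf.times
    below = f <= epsilon_n
    min_run = max(1, int(round(debounce_s * grf.rate)))
    events: list[float] = []
    i = 0
    n = f.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        if j - i >= min_run and i > 0:
            # interpolated epsilon-crossing between samples i-1 and i
            f0, f1 = f[i - 1], f[i]
            frac = (f0 - epsilon_n) / (f0 - f1) if f0 != f1 else 1.0
            tc = t[i - 1] + frac * (t[i] - t[i - 1])
            if refine == "extrapolate":
                tc = _extrapolate_zero(f, t, i, grf.rate, fallback=tc)
            events.append(float(tc))
        i = j
    if not events:
        raise EventDetectionError("no seat-off: rear-plate force never unloads")
    if expected_cycles is not None and len(events) != expected_cycles:
        raise EventDetectionError(
            f"expected {expected_cycles} seat-off events, found {len(events)} "
            f"at t={np.round(events, 3).tolist()}"
        )
    return np.asarray(events)


def _extrapolate_zero(f, t, idx, rate, fallback, lookback_s=1.5):
    """Regress the unloading ramp before sample ``idx`` and solve f = 0."""
    lo = max(0, idx - int(lookback_s * rate))
    seg_f = f[lo:idx]
    seg_t = t[lo:idx]
    if seg_f.size < 5:
        return fallback
    baseline = np.percentile(seg_f, 90)
    mask = (seg_f >= 0.10 * baseline) & (seg_f <= 0.60 * baseline)
    if mask.sum() < 5:
        return fallback
    b, a = np.polyfit(seg_t[mask], seg_f[mask], 1)
    if b >= 0:
        return fallback
    return -a / b


def cycle_windows(
    seat_off_times: np.ndarray, t_start: float, t_end: float
) -> list[tuple[float, float]]:
    """One analysis window per rise cycle, split midway between seat-offs."""
    so = np.sort(np.asarray(seat_off_times, dtype=float))
    edges = [t_start]
    edges += [0.5 * (a + b) for a, b in zip(so[:-1], so[1:])]
    edges.append(t_end)
    return [(edges[k], edges[k + 1]) for k in range(len(so))]


def detect_max_dorsiflexion(
    dorsi_deg: np.ndarray,
    times: np.ndarray,
    t_seat_off: float,
    t_window_end: float,
) -> float:
    """Time of maximum ankle dorsiflexion in (seat-off, window end].

    Ties resolve to the earliest sample.
    """
    mask = (times > t_seat_off) & (times <= t_window_end)
    if not mask.any():
        raise EventDetectionError("empty search window for max dorsiflexion")
    seg = dorsi_deg[mask]
    if np.isnan(seg).all():
        raise EventDetectionError("dorsiflexion series all-missing in window")
    k = int(np.nanargmax(seg))  # argmax returns the first maximum
    return float(times[mask][k])


# ---------------------------------------------------------------------------
# per-cycle indices


def com_velocity(
    com: np.ndarray, times: np.ndarray, t_seat_off: float, t_max_dorsi: float
) -> float:
    """Mean forward (y) COM velocity from seat-off to max dorsiflexion."""
    if t_max_dorsi <= t_seat_off:
        raise ValidationError("max dorsiflexion must follow seat-off")
    y = com[:, 1]
    y0 = float(np.interp(t_seat_off, times, y))
    y1 = float(np.interp(t_max_dorsi, times, y))
    return (y1 - y0) / (t_max_dorsi - t_seat_off)


def com_bos_distance(
    markers: MarkerTrajectorySet, com: np.ndarray, t_seat_off: float
) -> float:
    """Signed forward distance from the BOS trailing edge to the COM.

    The trailing edge is the rearmost heel marker (smaller y); negative
    means the COM is behind the heel line at seat-off.
    """
    times = markers.times
    com_y = float(np.interp(t_seat_off, times, com[:, 1]))
    heels = [float(np.interp(t_seat_off, times, markers.get(m)[:, 1]))
             for m in ("LHEE", "RHEE")]
    return com_y - min(heels)


def deepest_trunk_flexion(
    trunk_deg: np.ndarray, times: np.ndarray, window: tuple[float, float]
) -> float:
    """Per-cycle deepest (maximum) trunk flexion within a window, degrees."""
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any() or np.isnan(trunk_deg[mask]).all():
        raise EventDetectionError("no trunk-angle samples in cycle window")
    return float(np.nanmax(trunk_deg[mask]))
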