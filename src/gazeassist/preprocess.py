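"""Synchronization, smoothing and marker gap interpolation.

Force-plate data (1,000 Hz) are resampled onto the motion-capture time
base (100 Hz, i.e. 10 ms spacing) with an anti-alias low-pass before
decimation. Both streams are then smoothed with a zero-phase (forward-
backward) Butterworth filter: 6 Hz cutoff for marker coordinates, 18 Hz
for ground reaction forces, 4th order by default. Short marker gaps are
filled by cubic splines over neighbouring valid samples; longer gaps are
left missing and reported.

Processing order in the pipeline is synchronize -> gap-fill -> smooth, so
that splines are fit on raw (not filtered) neighbourhoods.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .core import ForcePlateSeries, MarkerTrajectorySet, ValidationError

DEFAULT_MARKER_CUTOFF_HZ = 6.0
DEFAULT_GRF_CUTOFF_HZ = 18.0
DEFAULT_FILTER_ORDER = 4
DEFAULT_MAX_GAP_S = 0.2


def synchronize(
    grf: ForcePlateSeries, markers: MarkerTrajectorySet
) -> ForcePlateSeries:
    """Resample force-plate data onto the marker time base.

    Anti-alias FIR filtering (polyphase resampling) is applied before
    decimation; a constant signal is preserved exactly. Returns a new
    :class:`ForcePlateSeries` at the marker rate whose samples coincide
    with marker frame times.
    """
    if grf.rate < markers.rate:
        raise ValidationError(
            f"force-plate rate {grf.rate} Hz below marker rate {markers.rate} Hz"
        )
    g_times = grf.times
    m_times = markers.times
    if g_times[-1] < m_times[0] or m_times[-1] < g_times[0]:
        raise ValidationError("force-plate and marker time ranges do not overlap")
    if grf.rate == markers.rate and abs(grf.t0 - markers.t0) < 0.5 / grf.rate:
        return grf.copy()

    ratio = Fraction(markers.rate / grf.rate).limit_denominator(10_000)
    n, p = grf.forces.shape[:2]
    flat = grf.forces.reshape(n, p * 3)
    res = signal.resample_poly(flat, ratio.numerator, ratio.denominator, axis=0)
    out_rate = grf.rate * ratio.numerator / ratio.denominator
    out_times = grf.t0 + np.arange(res.shape[0]) / out_rate

    # align onto marker frame times (linear interp handles any t0 offset)
    target = m_times[(m_times >= g_times[0]) & (m_times <= g_times[-1])]
    aligned = np.empty((target.size, p * 3))
    for j in range(p * 3):
        aligned[:, j] = np.interp(target, out_times, res[:, j])
    return ForcePlateSeries(
        plate_ids=grf.plate_ids,
        forces=aligned.reshape(target.size, p, 3),
        rate=markers.rate,
        t0=float(target[0]),
        rear_plates=grf.rear_plates,
        plate_size_mm=grf.plate_size_mm,
    )


def lowpass_filter(
    series: np.ndarray,
    cutoff_hz: float,
    rate: float,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0.

    Applied forward-backward (``filtfilt``), so the effective magnitude
    response is the squared Butterworth response and the phase lag is
    zero; DC gain is exactly 1. NaN runs (missing marker spans) are left
    in place and each contiguous valid run is filtered independently.
    """
    nyq = rate / 2.0
    if cutoff_hz >= nyq:
        raise ValidationError(f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz")
    if cutoff_hz <= 0:
        raise ValidationError("cutoff must be positive")
    b, a = signal.butter(order, cutoff_hz / nyq)
    x = np.asarray(series, dtype=float)
    flat = x.reshape(x.shape[0], -1)
    out = flat.copy()
    padlen = 3 * (max(len(a), len(b)) - 1)
    for j in range(flat.shape[1]):
        col = flat[:, j]
        valid = ~np.isnan(col)
        if valid.all():
            out[:, j] = signal.filtfilt(b, a, col)
            continue
        for start, stop in _runs(valid):
            if stop - start > padlen:
                out[start:stop, j] = signal.filtfilt(b, a, col[start:stop])
    return out.reshape(x.shape)


def filter_markers(
    markers: MarkerTrajectorySet,
    cutoff_hz: float = DEFAULT_MARKER_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> MarkerTrajectorySet:
    pos = lowpass_filter(markers.positions, cutoff_hz, markers.rate, order)
    return MarkerTrajectorySet(markers.marker_names, pos, markers.rate, markers.t0)


def filter_grf(
    grf: ForcePlateSeries,
    cutoff_hz: float = DEFAULT_GRF_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> ForcePlateSeries:
    forces = lowpass_filter(grf.forces, cutoff_hz, grf.rate, order)
    out = grf.copy()
    out.forces = forces
    return out


def interpolate_gaps(
    markers: MarkerTrajectorySet,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    neighbors: int = 5,
) -> tuple[MarkerTrajectorySet, list[dict]]:
    """Fill short missing runs by cubic splines over neighbouring samples.

    Gaps longer than ``max_gap_s`` (and markers missing entirely) are left
    as NaN and returned in the report: a list of dicts with marker name,
    start frame and length. Spline fitting uses up to ``neighbors`` valid
    samples on each side; with fewer than two on a side it falls back to
    linear interpolation where possible.
    """
    max_len = int(round(max_gap_s * markers.rate))
    pos = markers.positions.copy()
    report: list[dict] = []
    for mi, name in enumerate(markers.marker_names):
        col = pos[:, mi, :]
        valid = ~np.isnan(col[:, 0])
        if valid.all():
            continue
        if not valid.any():
            report.append({"marker": name, "start": 0, "length": col.shape[0],
                           "filled": False, "reason": "entirely missing"})
            continue
        vidx = np.flatnonzero(valid)
        for start, stop in _runs(~valid):
            length = stop - start
            left = vidx[vidx < start]
            right = vidx[vidx >= stop]
            fillable = (
                length <= max_len and left.size >= 2 and right.size >= 2
            )
            if not fillable:
                report.append({"marker": name, "start": int(start),
                               "length": int(length), "filled": False,
                               "reason": "gap too long or at boundary"})
                continue
            sup = np.concatenate([left[-neighbors:], right[:neighbors]])
            cs = CubicSpline(sup / markers.rate, col[sup, :], axis=0)
            col[start:stop, :] = cs(np.arange(start, stop) / markers.rate)
            report.append({"marker": name, "start": int(start),
                           "length": int(length), "filled": True})
    return (
        MarkerTrajectorySet(markers.marker_names, pos, markers.rate, markers.t0),
        report,
    )


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs in a boolean vector."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return
    d = np.diff(m.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    stops = list(np.flatnonzero(d == -1) + 1)
    if m[0]:
        starts.insert(0, 0)
    if m[-1]:
        stops.append(m.size)
    yield from zip(starts, stops)
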