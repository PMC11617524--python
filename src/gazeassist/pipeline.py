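"""End-to-end per-trial processing and cohort-level analysis.

Per trial: synchronize forces onto the marker clock, reconstruct occluded
ASIS markers from the sacral jig, fill short marker gaps, smooth both
streams, detect the five seat-off events and per-cycle maximum ankle
dorsiflexion, and extract the three kinematic indices (trial value = mean
over cycles) plus the four AOI gaze metrics over the support period.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from . import gaze_metrics as gm
from . import kinematics as kin
from . import preprocess as pp
from .anthropometry import SegmentSet, default_segments
from .core import KinematicIndices, TrialDataset


@dataclass
class PipelineConfig:
    """Tunable processing parameters (config-file keys mirror the fields)."""

    marker_cutoff_hz: float = pp.DEFAULT_MARKER_CUTOFF_HZ
    grf_cutoff_hz: float = pp.DEFAULT_GRF_CUTOFF_HZ
    filter_order: int = pp.DEFAULT_FILTER_ORDER
    max_gap_s: float = pp.DEFAULT_MAX_GAP_S
    seat_off_epsilon_n: float = kin.DEFAULT_SEAT_OFF_EPSILON_N
    debounce_s: float = kin.DEFAULT_DEBOUNCE_S
    seat_off_refine: str | None = "extrapolate"
    ivt_velocity_threshold_dps: float = gm.DEFAULT_VELOCITY_THRESHOLD_DPS
    ivt_min_fixation_ms: float = gm.DEFAULT_MIN_FIXATION_MS
    chin_offset_m: float = gm.DEFAULT_CHIN_OFFSET_M

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    def to_dict(self) -> dict:
        return asdict(self)


def preprocess_trial(
    trial: TrialDataset, config: PipelineConfig | None = None
):
    """Synchronize, reconstruct, gap-fill and smooth one trial's streams."""
    cfg = config or PipelineConfig()
    grf = pp.synchronize(trial.grf, trial.markers)
    pose = kin.calibrate_virtual_asis(trial.static)
    markers, _ = kin.reconstruct_asis(trial.markers, pose)
    markers, gap_report = pp.interpolate_gaps(markers, cfg.max_gap_s)
    markers = pp.filter_markers(markers, cfg.marker_cutoff_hz, cfg.filter_order)
    grf = pp.filter_grf(grf, cfg.grf_cutoff_hz, cfg.filter_order)
    return markers, grf, gap_report


def trial_kinematic_indices(
    trial: TrialDataset,
    config: PipelineConfig | None = None,
    segments: SegmentSet | None = None,
    _pre=None,
) -> KinematicIndices:
    """The three per-trial indices from the fully processed streams."""
    cfg = config or PipelineConfig()
    markers, grf, _ = _pre if _pre is not None else preprocess_trial(trial, cfg)
    segments = segments or default_segments()

    expected = trial.meta.get("n_cycles")
    seat_offs = kin.detect_seat_off(
        grf, cfg.seat_off_epsilon_n, cfg.debounce_s,
        expected_cycles=expected, refine=cfg.seat_off_refine,
    )
    times = markers.times
    windows = kin.cycle_windows(seat_offs, times[0], times[-1])
    trunk = kin.trunk_angle(markers)
    dorsi = kin.ankle_dorsiflexion(markers)
    com = kin.whole_body_com(markers, segments)

    deep, vel, dist, t_mds = [], [], [], []
    for t_so, (w0, w1) in zip(seat_offs, windows):
        t_md = kin.detect_max_dorsiflexion(dorsi, times, t_so, w1)
        t_mds.append(t_md)
        deep.append(kin.deepest_trunk_flexion(trunk, times, (w0, w1)))
        vel.append(kin.com_velocity(com, times, t_so, t_md))
        dist.append(kin.com_bos_distance(markers, com, t_so))
    return KinematicIndices(
        deepest_trunk_flexion_deg=float(np.mean(deep)),
        com_bos_distance_m=float(np.mean(dist)),
        com_velocity_ms=float(np.mean(vel)),
        seat_off_times_s=np.asarray(seat_offs),
        max_dorsiflexion_times_s=np.asarray(t_mds),
    )


def process_trial(
    trial: TrialDataset, config: PipelineConfig | None = None
) -> tuple[dict, pd.DataFrame]:
    """Kinematic-index row and gaze-metric rows for one trial."""
    cfg = config or PipelineConfig()
    pre = preprocess_trial(trial, cfg)
    indices = trial_kinematic_indices(trial, cfg, _pre=pre)
    row = {
        "participant": trial.participant_id,
        "group": trial.group,
        "trial": trial.trial_id,
        **indices.as_row(),
    }
    gaze = gm.trial_gaze_metrics(
        trial, pre[0], cfg.ivt_velocity_threshold_dps,
        cfg.ivt_min_fixation_ms, cfg.chin_offset_m,
    )
    return row, gaze


def run_cohort(
    trials: Iterable[TrialDataset], config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Process an iterable of trials; returns (gaze metrics, kinematics).

    Streams trial by trial, so a lazily generated cohort never resides in
    memory at once.
    """
    kin_rows, gaze_frames = [], []
    for trial in trials:
        row, gaze = process_trial(trial, config)
        kin_rows.append(row)
        gaze_frames.append(gaze)
    if not kin_rows:
        raise ValueError("no trials to process")
    return pd.concat(gaze_frames, ignore_index=True), pd.DataFrame(kin_rows)


def analyze_directory(
    data_dir: str | Path, config: PipelineConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the pipeline over every trial bundle under ``data_dir``."""
    from .io_formats import read_trial_bundle

    data_dir = Path(data_dir)
    bundles = sorted(p.parent for p in data_dir.glob("*/meta.yaml"))
    if not bundles:
        raise FileNotFoundError(f"no trial bundles under {data_dir}")
    return run_cohort((read_trial_bundle(b) for b in bundles), config)
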