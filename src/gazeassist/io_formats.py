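"""Readers/writers for the canonical trial bundle, plus optional C3D input.

A trial bundle is a directory of plain-text files:

    markers.csv   frame, time_s, <MARKER>_X/_Y/_Z ... (37 markers, meters)
    static.csv    same dialect; short standing calibration capture
    grf.csv       time_s, plate_id, fx_n, fy_n, fz_n (long format, newtons)
    gaze.tsv      timestamp_ms, gaze_x, gaze_y, validity (tab-delimited,
                  mirroring vendor exports)
    meta.yaml     group, ids, seed, rates, units, script parameters

Missing marker samples are empty fields (never sentinel zeros). All
internal computation is SI; if ``meta.yaml`` declares ``units: mm`` the
marker positions are converted to meters on read. C3D reading is a
read-only on-ramp for real motion-capture files and requires the optional
``ezc3d`` dependency.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    ALL_MARKERS,
    ForcePlateSeries,
    GazeStream,
    MarkerTrajectorySet,
    TrialDataset,
)

_FLOAT_FMT = "%.12g"


class ParseError(ValueError):
    """Malformed bundle file; the message names the file and line."""


# ---------------------------------------------------------------------------
# canonical bundle


def _markers_to_frame(markers: MarkerTrajectorySet) -> pd.DataFrame:
    cols = {"frame": np.arange(markers.n_frames), "time_s": markers.times}
    for i, m in enumerate(markers.marker_names):
        for j, ax in enumerate("XYZ"):
            cols[f"{m}_{ax}"] = markers.positions[:, i, j]
    return pd.DataFrame(cols)


def _markers_from_frame(df: pd.DataFrame, path: Path, scale: float = 1.0
                        ) -> MarkerTrajectorySet:
    names = []
    for c in df.columns:
        if c.endswith("_X"):
            names.append(c[:-2])
    if not names:
        raise ParseError(f"{path}: no marker columns found")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1:
        d = np.diff(t)
        bad = np.flatnonzero(d <= 0)
        if bad.size:
            raise ParseError(
                f"{path}, line {bad[0] + 3}: non-increasing time_s"
            )
    rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 100.0
    pos = np.empty((len(df), len(names), 3))
    for i, m in enumerate(names):
        for j, ax in enumerate("XYZ"):
            pos[:, i, j] = df[f"{m}_{ax}"].to_numpy(dtype=float) * scale
    return MarkerTrajectorySet(tuple(names), pos, round(rate, 6), float(t[0]))


def write_trial_bundle(trial: TrialDataset, path: str | Path) -> Path:
    """Write one trial as a canonical text bundle; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _markers_to_frame(trial.markers).to_csv(
        path / "markers.csv", index=False, float_format=_FLOAT_FMT, na_rep=""
    )
    _markers_to_frame(trial.static).to_csv(
        path / "static.csv", index=False, float_format=_FLOAT_FMT, na_rep=""
    )
    g = trial.grf
    rows = []
    for k, pid in enumerate(g.plate_ids):
        rows.append(pd.DataFrame({
            "time_s": g.times,
            "plate_id": pid,
            "fx_n": g.forces[:, k, 0],
            "fy_n": g.forces[:, k, 1],
            "fz_n": g.forces[:, k, 2],
        }))
    pd.concat(rows).to_csv(
        path / "grf.csv", index=False, float_format=_FLOAT_FMT, na_rep=""
    )
    pd.DataFrame({
        "timestamp_ms": trial.gaze.timestamps_ms,
        "gaze_x": trial.gaze.points[:, 0],
        "gaze_y": trial.gaze.points[:, 1],
        "validity": trial.gaze.validity.astype(int),
    }).to_csv(path / "gaze.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    meta = dict(trial.meta)
    meta.setdefault("units", "m")
    meta["rear_plates"] = list(g.rear_plates)
    with open(path / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return path


def read_trial_bundle(path: str | Path) -> TrialDataset:
    """Read a canonical bundle back into typed, unit-checked streams."""
    path = Path(path)
    with open(path / "meta.yaml") as fh:
        meta = yaml.safe_load(fh) or {}
    units = str(meta.get("units", "m")).lower()
    if units not in ("m", "mm"):
        raise ParseError(f"{path / 'meta.yaml'}: unsupported units {units!r}")
    scale = 0.001 if units == "mm" else 1.0
    meta["units"] = "m"

    markers = _markers_from_frame(
        pd.read_csv(path / "markers.csv"), path / "markers.csv", scale
    )
    static = _markers_from_frame(
        pd.read_csv(path / "static.csv"), path / "static.csv", scale
    )

    gdf = pd.read_csv(path / "grf.csv")
    plate_ids = tuple(pd.unique(gdf["plate_id"]))
    per_plate = []
    n = None
    for pid in plate_ids:
        sub = gdf[gdf["plate_id"] == pid]
        if n is None:
            n = len(sub)
            t = sub["time_s"].to_numpy(dtype=float)
        elif len(sub) != n:
            raise ParseError(f"{path / 'grf.csv'}: unequal plate lengths")
        per_plate.append(sub[["fx_n", "fy_n", "fz_n"]].to_numpy(dtype=float))
    forces = np.stack(per_plate, axis=1)
    rate = 1.0 / float(np.median(np.diff(t)))
    grf = ForcePlateSeries(
        plate_ids, forces, round(rate, 6), float(t[0]),
        rear_plates=tuple(meta.get("rear_plates", ("fp5", "fp6"))),
    )

    sdf = pd.read_csv(path / "gaze.tsv", sep="\t")
    ts = sdf["timestamp_ms"].to_numpy(dtype=float)
    d = np.diff(ts)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise ParseError(
            f"{path / 'gaze.tsv'}, line {bad[0] + 3}: non-monotone timestamp_ms"
        )
    rate_g = 1000.0 / float(np.median(d)) if ts.size > 1 else 50.0
    gaze = GazeStream(
        ts,
        sdf[["gaze_x", "gaze_y"]].to_numpy(dtype=float),
        sdf["validity"].to_numpy(dtype=int).astype(bool),
        rate=round(rate_g, 6),
    )
    meta.pop("rear_plates", None)
    return TrialDataset(markers, grf, gaze, static, meta)


# ---------------------------------------------------------------------------
# C3D (optional, read-only)


#: default label aliases: vendor label -> canonical marker name
DEFAULT_C3D_ALIASES = {"RASI": "RASI", "LASI": "LASI"}


def read_c3d(
    path: str | Path,
    alias_table: dict | None = None,
    required: tuple[str, ...] = ("LASI", "RASI", "SJ1", "SJ2", "SJ3"),
) -> tuple[MarkerTrajectorySet, ForcePlateSeries]:
    """Read marker and analog force data from a C3D motion-capture file.

    Labels are mapped to the canonical marker names through
    ``alias_table`` (vendor label -> canonical name); unmapped labels keep
    their own name. Raises if any ``required`` marker is absent after
    mapping (the ASIS and jig markers are needed for the calibration
    pose), listing the missing labels. Requires the optional ezc3d
    dependency.
    """
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "C3D support requires the optional 'ezc3d' package "
            "(pip install gazeassist[c3d])"
        ) from exc

    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in
              c3d["parameters"]["POINT"]["LABELS"]["value"]]
    alias = dict(alias_table or {})
    names = tuple(alias.get(lbl, lbl) for lbl in labels)
    missing = [m for m in required if m not in names]
    if missing:
        raise ParseError(f"{path}: required markers missing: {missing}")

    rate = float(c3d["header"]["points"]["frame_rate"])
    pts = np.asarray(c3d["data"]["points"])  # (4, n_markers, n_frames)
    pos = np.transpose(pts[:3], (2, 1, 0)).astype(float)
    unit = "mm"
    try:
        unit = str(c3d["parameters"]["POINT"]["UNITS"]["value"][0]).strip()
    except (KeyError, IndexError):
        pass
    if unit.lower() == "mm":
        pos = pos / 1000.0
    markers = MarkerTrajectorySet(names, pos, rate)

    analog_rate = float(c3d["header"]["analogs"]["frame_rate"])
    analogs = np.asarray(c3d["data"]["analogs"])  # (1, n_chan, n_samples)
    n_chan = analogs.shape[1]
    n_plates = max(n_chan // 3, 1)
    forces = np.zeros((analogs.shape[2], n_plates, 3))
    for p in range(n_plates):
        for j in range(3):
            ch = 3 * p + j
            if ch < n_chan:
                forces[:, p, j] = analogs[0, ch, :]
    plate_ids = tuple(f"fp{i + 1}" for i in range(n_plates))
    rear = tuple(p for p in ("fp5", "fp6") if p in plate_ids) or plate_ids[:1]
    grf = ForcePlateSeries(plate_ids, forces, analog_rate, rear_plates=rear)
    return markers, grf


# ---------------------------------------------------------------------------
# config


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
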