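"""Core in-memory containers for trial data.

All internal computation is in SI units: positions in meters, forces in
newtons, times in seconds (gaze timestamps in milliseconds, mirroring
vendor exports), angles in degrees where reported.

Coordinate convention: y is the forward (anterior) direction and positive,
z is up, x is lateral-right.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field

import numpy as np

#: Marker set: 34 body markers plus 3 markers on a sacral jig.
BODY_MARKERS: tuple[str, ...] = (
    "LFHD", "RFHD", "LBHD", "RBHD",          # head
    "CLAV", "STRN", "T2", "T7",              # trunk
    "LSHO", "RSHO",                          # acromion
    "LELB", "RELB",                          # elbow
    "LWRA", "LWRB", "RWRA", "RWRB",          # wrist
    "LASI", "RASI", "LPSI", "RPSI",          # pelvis
    "LHIP", "RHIP",                          # hip joint
    "LTHI", "RTHI",                          # thigh wand
    "LKNE", "RKNE",                          # knee
    "LTIB", "RTIB",                          # shank wand
    "LANK", "RANK",                          # lateral malleolus
    "LHEE", "RHEE",                          # heel
    "LTOE", "RTOE",                          # 2nd metatarsal head
)
JIG_MARKERS: tuple[str, ...] = ("SJ1", "SJ2", "SJ3")
ALL_MARKERS: tuple[str, ...] = BODY_MARKERS + JIG_MARKERS

AOI_NAMES: tuple[str, ...] = ("head", "neck", "trunk", "hip", "knee", "foot")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class MarkerTrajectorySet:
    """3D marker trajectories on a shared time base.

    ``positions`` has shape (n_frames, n_markers, 3); missing samples are
    NaN (never sentinel zeros).
    """

    marker_names: tuple[str, ...]
    positions: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.marker_names = tuple(self.marker_names)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.rate <= 0:
            raise ValidationError("marker frame rate must be > 0")
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValidationError("positions must have shape (frames, markers, 3)")
        if self.positions.shape[1] != len(self.marker_names):
            raise ValidationError("marker_names length must match positions")
        self._index = {m: i for i, m in enumerate(self.marker_names)}

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def get(self, marker: str) -> np.ndarray:
        """Trajectory of one marker, shape (n_frames, 3)."""
        try:
            return self.positions[:, self._index[marker], :]
        except KeyError:
            raise KeyError(f"unknown marker {marker!r}") from None

    def has(self, marker: str) -> bool:
        return marker in self._index

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            self.marker_names, self.positions.copy(), self.rate, self.t0
        )

    def frame_at(self, t: float) -> int:
        """Index of the frame nearest to time ``t``."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.n_frames - 1)


@dataclass
class ForcePlateSeries:
    """Force vectors per plate on a shared time base.

    ``forces`` has shape (n_samples, n_plates, 3) ordered (Fx, Fy, Fz) in
    newtons; ``rear_plates`` names the two plates under the chair.
    """

    plate_ids: tuple[str, ...]
    forces: np.ndarray
    rate: float
    t0: float = 0.0
    rear_plates: tuple[str, ...] = ("fp5", "fp6")
    plate_size_mm: tuple[float, float] = (400.0, 600.0)

    def __post_init__(self) -> None:
        self.plate_ids = tuple(self.plate_ids)
        self.rear_plates = tuple(self.rear_plates)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.rate <= 0:
            raise ValidationError("force-plate rate must be > 0")
        if self.forces.ndim != 3 or self.forces.shape[2] != 3:
            raise ValidationError("forces must have shape (samples, plates, 3)")
        if self.forces.shape[1] != len(self.plate_ids):
            raise ValidationError("plate_ids length must match forces")
        missing = set(self.rear_plates) - set(self.plate_ids)
        if missing:
            raise ValidationError(f"rear plates {sorted(missing)} not among plate ids")
        self._index = {p: i for i, p in enumerate(self.plate_ids)}

    @property
    def n_samples(self) -> int:
        return self.forces.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def vertical(self, plate: str) -> np.ndarray:
        return self.forces[:, self._index[plate], 2]

    def rear_vertical_total(self) -> np.ndarray:
        """Summed vertical force on the two plates under the chair."""
        idx = [self._index[p] for p in self.rear_plates]
        return self.forces[:, idx, 2].sum(axis=1)

    def copy(self) -> "ForcePlateSeries":
        return dataclasses.replace(self, forces=self.forces.copy())


@dataclass
class GazeStream:
    """Gaze samples in the body-anchored analysis plane.

    ``points`` has shape (n, 2): (horizontal, vertical) position in meters;
    the vertical coordinate is lab height, which is what the AOI bands are
    defined on. Timestamps are milliseconds, strictly increasing.
    """

    timestamps_ms: np.ndarray
    points: np.ndarray
    validity: np.ndarray
    rate: float = 50.0

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValidationError("gaze points must have shape (n, 2)")
        n = self.timestamps_ms.shape[0]
        if self.points.shape[0] != n or self.validity.shape[0] != n:
            raise ValidationError("gaze arrays must share one length")
        if n > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise ValidationError("gaze timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.timestamps_ms.shape[0]


@dataclass
class TrialDataset:
    """One assisted stand/sit trial: all streams plus metadata.

    ``static`` is a short standing capture with every marker visible, used
    to calibrate the sacral-jig -> ASIS offsets.
    """

    markers: MarkerTrajectorySet
    grf: ForcePlateSeries
    gaze: GazeStream
    static: MarkerTrajectorySet
    meta: dict = field(default_factory=dict)

    @property
    def group(self) -> str:
        return self.meta.get("group", "unknown")

    @property
    def participant_id(self) -> str:
        return str(self.meta.get("participant_id", ""))

    @property
    def trial_id(self) -> str:
        return str(self.meta.get("trial_id", ""))


@dataclass(frozen=True)
class Fixation:
    """A single fixation: onset and duration in ms, centroid in plane meters."""

    start_ms: float
    duration_ms: float
    centroid: tuple[float, float]

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.duration_ms

    @property
    def midpoint_ms(self) -> float:
        return self.start_ms + 0.5 * self.duration_ms


FixationSequence = list  # list[Fixation], time-ordered, non-overlapping


@dataclass
class KinematicIndices:
    """Per-trial kinematic indices (trial value = mean over the 5 cycles)."""

    deepest_trunk_flexion_deg: float
    com_bos_distance_m: float
    com_velocity_ms: float
    seat_off_times_s: np.ndarray
    max_dorsiflexion_times_s: np.ndarray

    def as_row(self) -> dict:
        return {
            "deepest_trunk_flexion_deg": self.deepest_trunk_flexion_deg,
            "com_bos_distance_m": self.com_bos_distance_m,
            "com_velocity_ms": self.com_velocity_ms,
            "n_cycles": len(np.atleast_1d(self.seat_off_times_s)),
        }


def require(condition: bool, message: str) -> None:
    if not condition:
        raise ValidationError(message)


def split_seed(seed: int, *keys) -> np.random.Generator:
    """Hierarchically derived RNG: one master seed, independent substreams.

    Adding a participant or trial does not perturb the streams of the
    others because each (seed, *keys) path seeds its own SeedSequence.
    """
    hashed = [
        zlib.crc32(k.encode()) % (2**31) if isinstance(k, str) else int(k)
        for k in keys
    ]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *hashed]))
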