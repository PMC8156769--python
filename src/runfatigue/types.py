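"""Shared domain types for multi-IMU running sessions.

A recording covers one athlete's track session measured with eight
body-worn inertial units (sternum, pelvis, both thighs, tibias and feet)
plus model-derived sagittal joint angles and the pelvis forward velocity.
Locations are addressed by the codes L1..L8:

====  ============
code  segment
====  ============
L1    sternum
L2    pelvis
L3    right thigh
L4    left thigh
L5    right tibia
L6    left tibia
L7    right foot
L8    left foot
====  ============

Conventions: indices are 0-based, intervals half-open ``[start, end)``;
joint angles are in degrees with flexion positive; "pitch" angular
velocity is the medio-lateral-axis (y) gyroscope component, forward
rotation positive, in deg/s; accelerations are in m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

#: Location code -> segment name.
LOCATIONS: dict[str, str] = {
    "L1": "sternum",
    "L2": "pelvis",
    "L3": "thigh_r",
    "L4": "thigh_l",
    "L5": "tibia_r",
    "L6": "tibia_l",
    "L7": "foot_r",
    "L8": "foot_l",
}

#: Canonical location order.
LOCATION_CODES: tuple[str, ...] = tuple(LOCATIONS)

#: Sagittal joints, right before left at each level (hip, knee, ankle).
JOINTS: tuple[str, ...] = (
    "hip_r", "hip_l", "knee_r", "knee_l", "ankle_r", "ankle_l",
)

#: Sensor pair required to compute each joint angle.
JOINT_SENSORS: dict[str, frozenset[str]] = {
    "hip_r": frozenset({"L2", "L3"}),
    "hip_l": frozenset({"L2", "L4"}),
    "knee_r": frozenset({"L3", "L5"}),
    "knee_l": frozenset({"L4", "L6"}),
    "ankle_r": frozenset({"L5", "L7"}),
    "ankle_l": frozenset({"L6", "L8"}),
}

#: Number of samples every gait-cycle curve is resampled to.
CYCLE_POINTS: int = 150

#: Fatigue condition labels.
LABELS: tuple[str, ...] = ("no_fatigue", "mild_fatigue", "heavy_fatigue")
EXCLUDED: str = "excluded"


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != ndim:
        raise ValidationError(f"{name}: expected {ndim}-D array, got {arr.ndim}-D")
    return arr


@dataclass
class SessionRecording:
    """One subject's full instrumented track session.

    ``lap_starts``/``lap_ends`` delimit the 400 m laps as half-open sample
    intervals; consecutive laps of the same run abut, while a standing gap
    may separate runs (the variable-length fatiguing bout between the
    constant-speed runs is represented only by that gap).
    ``run_of_lap[i]`` gives the run index (1 or 3) of lap ``i`` (0-based).
    """

    subject_id: str
    sampling_rate: float
    #: code -> {"accel": (N, 3) m/s^2, "angvel": (N, 3) deg/s}
    segment_streams: Mapping[str, Mapping[str, np.ndarray]]
    #: joint name -> (N,) sagittal angle, deg
    joint_streams: Mapping[str, np.ndarray]
    #: (N,) pelvis forward (sagittal) velocity, m/s
    pelvis_velocity: np.ndarray
    lap_starts: np.ndarray
    lap_ends: np.ndarray
    run_of_lap: Sequence[int]
    nominal_speed_kmh: float

    def __post_init__(self) -> None:
        self.pelvis_velocity = _as_float_array(self.pelvis_velocity, "pelvis_velocity", 1)
        self.lap_starts = np.asarray(self.lap_starts, dtype=int)
        self.lap_ends = np.asarray(self.lap_ends, dtype=int)
        self.run_of_lap = list(int(r) for r in self.run_of_lap)
        self.segment_streams = {
            code: {
                kind: _as_float_array(arr, f"segment_streams[{code}][{kind}]", 2)
                for kind, arr in streams.items()
            }
            for code, streams in self.segment_streams.items()
        }
        self.joint_streams = {
            name: _as_float_array(arr, f"joint_streams[{name}]", 1)
            for name, arr in self.joint_streams.items()
        }
        self.validate()

    # -- invariants -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.pelvis_velocity.shape[0])

    @property
    def n_laps(self) -> int:
        return int(self.lap_starts.shape[0])

    @property
    def nominal_speed_mps(self) -> float:
        return self.nominal_speed_kmh / 3.6

    def lap_in_run(self, lap_index: int) -> int:
        """1-based lap number within its own run for 0-based ``lap_index``."""
        run = self.run_of_lap[lap_index]
        return sum(1 for r in self.run_of_lap[: lap_index + 1] if r == run)

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate: must be > 0")
        if self.nominal_speed_kmh <= 0:
            raise ValidationError("nominal_speed_kmh: must be > 0")
        n = self.n_samples
        if n == 0:
            raise ValidationError("pelvis_velocity: streams must be non-empty")
        for code, streams in self.segment_streams.items():
            if code not in LOCATIONS:
                raise ValidationError(f"segment_streams: unknown location code {code!r}")
            for kind in ("accel", "angvel"):
                if kind not in streams:
                    raise ValidationError(f"segment_streams[{code}]: missing {kind!r}")
                arr = streams[kind]
                if arr.shape != (n, 3):
                    raise ValidationError(
                        f"segment_streams[{code}][{kind}]: shape {arr.shape} != ({n}, 3)"
                    )
        for name, arr in self.joint_streams.items():
            if name not in JOINTS:
                raise ValidationError(f"joint_streams: unknown joint {name!r}")
            if arr.shape != (n,):
                raise ValidationError(f"joint_streams[{name}]: length {arr.shape[0]} != {n}")
        if self.lap_starts.shape != self.lap_ends.shape:
            raise ValidationError("lap_starts/lap_ends: length mismatch")
        if self.n_laps:
            if np.any(self.lap_ends <= self.lap_starts):
                raise ValidationError("lap_ends: each lap must end after it starts")
            if np.any(np.diff(self.lap_starts) <= 0):
                raise ValidationError("lap_starts: must be strictly increasing")
            if np.any(self.lap_starts[1:] < self.lap_ends[:-1]):
                raise ValidationError("lap_starts: laps must not overlap")
            if self.lap_starts[0] < 0 or self.lap_ends[-1] > n:
                raise ValidationError("lap_boundaries: outside stream length")
        if len(self.run_of_lap) != self.n_laps:
            raise ValidationError("run_of_lap: one run index per lap required")
        for r in self.run_of_lap:
            if r not in (1, 2, 3):
                raise ValidationError(f"run_of_lap: invalid run index {r}")


@dataclass
class GaitCycle:
    """One stride, time-normalized to ``CYCLE_POINTS`` samples per curve.

    ``curves`` maps signal names (``"L5_accel_mag"``, ``"L5_angvel_pitch"``,
    ``"knee_r_angle"``, ...) to length-150 arrays.
    """

    side: str
    start_index: int
    end_index: int
    stride_time: float
    stride_distance: float
    curves: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValidationError(f"side: {self.side!r} not in {{'left', 'right'}}")
        if self.end_index <= self.start_index:
            raise ValidationError("end_index: must exceed start_index")
        if self.stride_time <= 0:
            raise ValidationError("stride_time: must be > 0")
        for name, arr in self.curves.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (CYCLE_POINTS,):
                raise ValidationError(
                    f"curves[{name}]: length {arr.shape} != ({CYCLE_POINTS},)"
                )
            self.curves[name] = arr


@dataclass
class StrideEvents:
    """Stride-level events detected within one running bout."""

    run_start: int
    run_end: int
    stride_peaks: np.ndarray            # downward pelvis-velocity peak indices
    initial_contacts: list[tuple[int, str]]  # (sample index, 'left'|'right')

    def __post_init__(self) -> None:
        self.stride_peaks = np.asarray(self.stride_peaks, dtype=int)
        idx = [i for i, _ in self.initial_contacts]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError("initial_contacts: indices must be strictly increasing")
        sides = [s for _, s in self.initial_contacts]
        if any(a == b for a, b in zip(sides, sides[1:])):
            raise ValidationError("initial_contacts: sides must alternate")
        for i in idx:
            if not (self.run_start <= i < self.run_end):
                raise ValidationError("initial_contacts: index outside run bounds")


@dataclass
class SensorConfiguration:
    """A subset of the eight IMU locations and what it can compute."""

    locations: frozenset[str]
    derived_joints: frozenset[str]
    feature_mask: tuple[str, ...]
    category: str

    @property
    def code_string(self) -> str:
        return " ".join(sorted(self.locations))


@dataclass
class FoldResult:
    """Outcome of one outer leave-one-subject-out fold."""

    left_out_subject: str
    confusion: np.ndarray               # 3x3 counts, rows = true, cols = predicted
    selected_features: list[str]        # ranked, best first
    accuracy: float


@dataclass
class EvalReport:
    """Nested leave-one-subject-out evaluation results for one configuration."""

    configuration: SensorConfiguration
    classes: tuple[str, ...]
    folds: list[FoldResult]
    aggregate_confusion: np.ndarray
    #: class -> {"sensitivity"|"specificity"|"precision"|"f1": (mean, std)}
    per_class_metrics: dict[str, dict[str, tuple[float, float]]]
    accuracy_mean: float
    accuracy_std: float

    def validate(self) -> None:
        cm = np.asarray(self.aggregate_confusion)
        if cm.shape != (len(self.classes),) * 2:
            raise ValidationError("aggregate_confusion: wrong shape")
        if np.any(cm < 0) or not np.issubdtype(cm.dtype, np.integer):
            raise ValidationError("aggregate_confusion: counts must be non-negative integers")
        total_folds = sum(f.confusion.sum() for f in self.folds)
        if total_folds != cm.sum():
            raise ValidationError("aggregate_confusion: total differs from per-fold totals")
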