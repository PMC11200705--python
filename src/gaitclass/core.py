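"""Shared domain types: recordings, gait-cycle windows, phase boundaries, metrics.

Conventions used throughout the package:

* sample indices are 0-based, intervals are half-open ``[start, end)``;
* the 48-channel layout stacks the 8 sensor sites in :data:`SITES` order,
  6 channels per site in :data:`CHANNELS` order;
* acceleration is carried in g, angular velocity in degrees per second;
* the binary class labels are ``"WA"`` (walking acquired, negative) and
  ``"NA"`` (not acquired, positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical sensor-site ordering; every 48-channel stack follows it.
SITES: tuple[str, ...] = (
    "chest",
    "lower_back",
    "left_wrist",
    "right_wrist",
    "left_thigh",
    "right_thigh",
    "left_ankle",
    "right_ankle",
)

#: Per-site channel ordering (acceleration in g, angular velocity in deg/s).
CHANNELS: tuple[str, ...] = (
    "acc_x",
    "acc_y",
    "acc_z",
    "gyr_roll",
    "gyr_pitch",
    "gyr_yaw",
)

N_SITES = len(SITES)
N_CHANNELS_PER_SITE = len(CHANNELS)
N_CHANNELS = N_SITES * N_CHANNELS_PER_SITE  # 48

#: Hardware measurement range of the sensors.
ACC_RANGE_G = 16.0
GYR_RANGE_DPS = 2000.0

TRIAL_10MWT = "10MWT"
TRIAL_TUG = "TUG"
TRIAL_TYPES = (TRIAL_10MWT, TRIAL_TUG)

LABEL_WA = "WA"
LABEL_NA = "NA"
LABELS = (LABEL_WA, LABEL_NA)

#: Class index used by the model head; NA is the positive class.
LABEL_TO_INDEX = {LABEL_WA: 0, LABEL_NA: 1}

ACC_COLUMNS = slice(0, 3)
GYR_COLUMNS = slice(3, 6)


def site_channel_slice(site: str) -> slice:
    """Half-open slice of ``site``'s 6 channels inside the 48-channel stack."""
    i = SITES.index(site)
    return slice(i * N_CHANNELS_PER_SITE, (i + 1) * N_CHANNELS_PER_SITE)


def channel_group_indices(axis: int) -> np.ndarray:
    """Channel indices of one modality/axis group across the 8 sites.

    ``axis`` indexes :data:`CHANNELS` (0..5); the returned 8 indices pick
    that channel at every site.
    """
    if not 0 <= axis < N_CHANNELS_PER_SITE:
        raise ValueError(f"axis must be in [0, {N_CHANNELS_PER_SITE}), got {axis}")
    return np.arange(axis, N_CHANNELS, N_CHANNELS_PER_SITE)


@dataclass
class ImuRecording:
    """One trial's synchronized 8-site recording.

    ``data`` maps site name to an ``(n, 6)`` float array in
    :data:`CHANNELS` column order.
    """

    subject_id: str
    trial_type: str
    trial_index: int
    sample_rate_hz: float
    data: dict[str, np.ndarray]

    def validate(self) -> "ImuRecording":
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")
        if set(self.data) != set(SITES):
            missing = sorted(set(SITES) - set(self.data))
            extra = sorted(set(self.data) - set(SITES))
            raise ValueError(f"bad site set: missing={missing} extra={extra}")
        lengths = {site: arr.shape[0] for site, arr in self.data.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"ragged channel lengths across sites: {lengths}")
        n = next(iter(lengths.values()))
        if n < 2:
            raise ValueError("recording must contain at least 2 samples")
        for site, arr in self.data.items():
            if arr.ndim != 2 or arr.shape[1] != N_CHANNELS_PER_SITE:
                raise ValueError(f"{site}: expected (n, 6) array, got {arr.shape}")
            if np.abs(arr[:, ACC_COLUMNS]).max(initial=0.0) > ACC_RANGE_G:
                raise ValueError(f"{site}: acceleration exceeds ±{ACC_RANGE_G} g")
            if np.abs(arr[:, GYR_COLUMNS]).max(initial=0.0) > GYR_RANGE_DPS:
                raise ValueError(
                    f"{site}: angular velocity exceeds ±{GYR_RANGE_DPS} deg/s"
                )
        return self

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[0]

    def stacked(self) -> np.ndarray:
        """``(n, 48)`` array with sites in canonical order."""
        return np.hstack([self.data[site] for site in SITES])

    def key(self) -> tuple[str, int]:
        return (self.trial_type, self.trial_index)


@dataclass
class TugPhases:
    """Six ordered TUG sub-phase intervals (half-open sample indices)."""

    sit_to_stand: tuple[int, int]
    walk1: tuple[int, int]
    turn1: tuple[int, int]
    walk2: tuple[int, int]
    turn2: tuple[int, int]
    stand_to_sit: tuple[int, int]

    def ordered(self) -> list[tuple[int, int]]:
        return [
            self.sit_to_stand,
            self.walk1,
            self.turn1,
            self.walk2,
            self.turn2,
            self.stand_to_sit,
        ]

    def validate(self) -> "TugPhases":
        phases = self.ordered()
        for (s, e) in phases:
            if not (0 <= s < e):
                raise ValueError(f"invalid phase interval ({s}, {e})")
        for (_, e_prev), (s_next, _) in zip(phases, phases[1:]):
            if s_next < e_prev:
                raise ValueError("TUG phases overlap or are out of order")
        if self.walk1 != (self.sit_to_stand[1], self.turn1[0]):
            raise ValueError("walk1 must span sit_to_stand.end .. turn1.start")
        if self.walk2 != (self.turn1[1], self.turn2[0]):
            raise ValueError("walk2 must span turn1.end .. turn2.start")
        return self


@dataclass
class TrialTruth:
    """Generator-known events of one trial (test oracle for segmentation)."""

    ic_left: np.ndarray
    ic_right: np.ndarray
    tug_phases: TugPhases | None = None

    def validate(self, n_samples: int) -> "TrialTruth":
        for name, ics in (("ic_left", self.ic_left), ("ic_right", self.ic_right)):
            ics = np.asarray(ics)
            if ics.size and (np.any(np.diff(ics) <= 0)):
                raise ValueError(f"{name} indices must be strictly increasing")
            if ics.size and (ics[0] < 0 or ics[-1] >= n_samples):
                raise ValueError(f"{name} indices out of range")
        if self.tug_phases is not None:
            self.tug_phases.validate()
        return self


@dataclass
class GroundTruth:
    """Per-subject ground truth: class label plus per-trial events."""

    class_label: str
    trials: dict[tuple[str, int], TrialTruth] = field(default_factory=dict)


@dataclass
class GaitCycleWindow:
    """One same-side gait cycle: a 48-channel slice of a walking phase."""

    subject_id: str
    trial_type: str
    trial_index: int
    side: str
    start: int
    end: int
    data: np.ndarray  # (length, 48)
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start

    def validate(self) -> "GaitCycleWindow":
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.end - self.start < 2:
            raise ValueError("gait cycle must span at least 2 samples")
        if self.data.shape != (self.end - self.start, N_CHANNELS):
            raise ValueError(
                f"data shape {self.data.shape} != ({self.end - self.start}, {N_CHANNELS})"
            )
        return self


@dataclass
class NormalizedSample:
    """Fixed-length model input: ``(length_max, 48)`` values in [0, 1].

    Positions at or beyond ``valid_length`` hold the padding constant 0.5.
    """

    matrix: np.ndarray
    subject_id: str
    label: str
    valid_length: int

    def validate(self) -> "NormalizedSample":
        if self.matrix.ndim != 2 or self.matrix.shape[1] != N_CHANNELS:
            raise ValueError(f"matrix must be (L, {N_CHANNELS}), got {self.matrix.shape}")
        if not (0 < self.valid_length <= self.matrix.shape[0]):
            raise ValueError("valid_length out of range")
        if self.matrix.min() < -1e-9 or self.matrix.max() > 1 + 1e-9:
            raise ValueError("normalized values must lie in [0, 1]")
        tail = self.matrix[self.valid_length:]
        if tail.size and not np.all(tail == 0.5):
            raise ValueError("padding tail must equal 0.5 exactly")
        return self


@dataclass
class ConfusionMatrix:
    """Binary confusion counts with NA as the positive class."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    def validate(self) -> "ConfusionMatrix":
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one count")
        return self

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def add(self, truth: str, predicted: str) -> None:
        if truth == LABEL_NA:
            if predicted == LABEL_NA:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted == LABEL_NA:
                self.fp += 1
            else:
                self.tn += 1


@dataclass
class Metrics:
    """Accuracy / sensitivity / specificity; NaN marks an undefined ratio."""

    accuracy: float
    sensitivity: float
    specificity: float

    def is_defined(self) -> bool:
        return not any(
            math.isnan(v) for v in (self.accuracy, self.sensitivity, self.specificity)
        )
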