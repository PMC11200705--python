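"""Raw recordings -> left gait-cycle windows.

Steps: cohort reading, 1 Hz high-pass on acceleration, initial-contact (IC)
detection from the differenced combined ankle acceleration, TUG sub-phase
segmentation from the lumbar angular velocity, walking-interval extraction,
and cycle slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.signal import butter, filtfilt, find_peaks

from .core import (
    ACC_COLUMNS,
    GaitCycleWindow,
    ImuRecording,
    SITES,
    TRIAL_10MWT,
    TRIAL_TUG,
    TRIAL_TYPES,
    TugPhases,
    site_channel_slice,
)
from .synthetic import CSV_COLUMNS, MANIFEST_NAME


# ---------------------------------------------------------------------------
# cohort reading

@dataclass
class SubjectData:
    subject_id: str
    label: str
    recordings: list[ImuRecording]


def read_cohort(manifest_path) -> list[SubjectData]:
    """Load a cohort from the manifest written by ``synthetic.write_cohort``.

    Trials marked ``present: false`` are skipped; a referenced trial with a
    missing per-site CSV is an error naming the site and trial.
    """
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    fs = float(manifest["sample_rate_hz"])

    cohort = []
    for entry in manifest["subjects"]:
        recordings = []
        for trial in entry["trials"]:
            if not trial.get("present", True):
                continue
            trial_type = trial["trial_type"]
            if trial_type not in TRIAL_TYPES:
                raise ValueError(
                    f"{entry['id']}: unknown trial type {trial_type!r}"
                )
            trial_dir = root / trial["dir"]
            data = {}
            for site in SITES:
                path = trial_dir / f"{site}.csv"
                if not path.exists():
                    raise FileNotFoundError(
                        f"{entry['id']} {trial_type}_{trial['trial_index']}: "
                        f"missing file for site {site!r}: {path}"
                    )
                frame = pd.read_csv(path)
                if list(frame.columns) != CSV_COLUMNS:
                    raise ValueError(f"{path}: unexpected columns {list(frame.columns)}")
                data[site] = frame[CSV_COLUMNS[1:]].to_numpy(dtype=float)
            lengths = {site: arr.shape[0] for site, arr in data.items()}
            if len(set(lengths.values())) != 1:
                raise ValueError(
                    f"{entry['id']} {trial_type}_{trial['trial_index']}: "
                    f"ragged site lengths {lengths}"
                )
            recordings.append(
                ImuRecording(
                    subject_id=entry["id"],
                    trial_type=trial_type,
                    trial_index=int(trial["trial_index"]),
                    sample_rate_hz=fs,
                    data=data,
                ).validate()
            )
        cohort.append(SubjectData(entry["id"], entry["label"], recordings))
    return cohort


# ---------------------------------------------------------------------------
# filtering

def highpass_acceleration(recording: ImuRecording, cutoff_hz: float = 1.0,
                          order: int = 4) -> ImuRecording:
    """Zero-phase Butterworth high-pass on the acceleration channels only.

    Removes the gravity component; angular velocity passes through
    untouched.  Output length equals input length.
    """
    nyquist = recording.sample_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    b, a = butter(order, cutoff_hz, btype="highpass", fs=recording.sample_rate_hz)
    data = {}
    for site, arr in recording.data.items():
        out = arr.copy()
        out[:, ACC_COLUMNS] = filtfilt(b, a, arr[:, ACC_COLUMNS], axis=0)
        data[site] = out
    return replace(recording, data=data)


def combined_acceleration(acc_x: np.ndarray, acc_y: np.ndarray,
                          acc_z: np.ndarray) -> np.ndarray:
    """Euclidean norm of the three acceleration axes, elementwise."""
    acc_x, acc_y, acc_z = map(np.asarray, (acc_x, acc_y, acc_z))
    if not (acc_x.shape == acc_y.shape == acc_z.shape):
        raise ValueError("acceleration axes must have equal length")
    return np.sqrt(acc_x ** 2 + acc_y ** 2 + acc_z ** 2)


# ---------------------------------------------------------------------------
# initial contacts

@dataclass
class IcParams:
    """Peak-picking knobs for IC detection.

    ``min_separation_s`` suppresses within-cycle secondary peaks (per-side
    cycles in this population last >= ~1 s); the prominence floor is
    relative to the differenced series' robust spread, so detection is
    invariant to overall amplitude scaling.  The default factor sits between
    the prominence of smooth gait ripple (~3x the robust sd) and that of
    impact transients (>~7x); ``height_factor`` additionally rejects
    noise peaks in quiet (non-walking) stretches, whose prominence can be
    large but whose absolute height stays near the noise floor.
    """

    min_separation_s: float = 0.6
    prominence_factor: float = 4.0
    height_factor: float = 5.0


def detect_initial_contacts(ankle: np.ndarray, sample_rate_hz: float,
                            params: IcParams | None = None) -> np.ndarray:
    """IC sample indices from one ankle's (already high-passed) channels.

    ``ankle`` is an ``(n, >=3)`` array whose first three columns are the
    acceleration axes.  The combined acceleration is differenced by one
    sample and the periodic peaks of that series are the ICs.
    """
    params = params or IcParams()
    ankle = np.asarray(ankle)
    comb = combined_acceleration(ankle[:, 0], ankle[:, 1], ankle[:, 2])
    if comb.shape[0] < 3:
        raise ValueError("recording too short for IC detection")
    diff = np.diff(comb)
    mad = np.median(np.abs(diff - np.median(diff)))
    robust_sd = 1.4826 * mad
    if robust_sd == 0.0:
        return np.array([], dtype=int)
    distance = max(int(round(params.min_separation_s * sample_rate_hz)), 1)
    peaks, _ = find_peaks(
        diff,
        distance=distance,
        prominence=params.prominence_factor * robust_sd,
        height=params.height_factor * robust_sd,
    )
    return peaks.astype(int)


# ---------------------------------------------------------------------------
# TUG sub-phases

def _threshold_extent(x_norm: np.ndarray, anchor: int, threshold: float) -> tuple[int, int]:
    """Contiguous half-open run around ``anchor`` where ``x_norm >= threshold``."""
    s = anchor
    while s > 0 and x_norm[s - 1] >= threshold:
        s -= 1
    e = anchor
    n = x_norm.shape[0]
    while e < n - 1 and x_norm[e + 1] >= threshold:
        e += 1
    return s, e + 1


def segment_tug_phases(lumbar: np.ndarray, sample_rate_hz: float,
                       threshold: float = 0.1) -> TugPhases:
    """Six TUG sub-phases from the lumbar angular velocity.

    ``lumbar`` is an ``(n, 6)`` channel array in canonical order; columns 4
    and 5 are the pitch and yaw rates.  Sit-to-stand / stand-to-sit anchor at
    the global pitch maximum / minimum, the two turns at yaw absolute-value
    maxima; each phase spans the contiguous region around its anchor where
    the channel, normalized by its own trial-wide maximum absolute value,
    stays at or above ``threshold``.
    """
    lumbar = np.asarray(lumbar)
    pitch = lumbar[:, 4]
    yaw = lumbar[:, 5]
    pitch_norm = np.abs(pitch) / np.abs(pitch).max()
    yaw_norm = np.abs(yaw) / np.abs(yaw).max()

    s2s_anchor = int(np.argmax(pitch))
    s2sit_anchor = int(np.argmin(pitch))
    sit_to_stand = _threshold_extent(pitch_norm, s2s_anchor, threshold)
    stand_to_sit = _threshold_extent(pitch_norm, s2sit_anchor, threshold)

    turn_a_anchor = int(np.argmax(yaw_norm))
    turn_a = _threshold_extent(yaw_norm, turn_a_anchor, threshold)
    masked = yaw_norm.copy()
    masked[turn_a[0]:turn_a[1]] = 0.0
    if masked.max() < threshold:
        raise ValueError("fewer than two yaw turning bursts found")
    turn_b_anchor = int(np.argmax(masked))
    turn_b = _threshold_extent(yaw_norm, turn_b_anchor, threshold)
    turn1, turn2 = sorted([turn_a, turn_b])
    if turn1[1] > turn2[0]:
        raise ValueError("turning bursts overlap")

    phases = TugPhases(
        sit_to_stand=sit_to_stand,
        walk1=(sit_to_stand[1], turn1[0]),
        turn1=turn1,
        walk2=(turn1[1], turn2[0]),
        turn2=turn2,
        stand_to_sit=stand_to_sit,
    )
    try:
        phases.validate()
    except ValueError as exc:
        raise ValueError(f"TUG phase anchors out of order: {exc}") from exc
    return phases


# ---------------------------------------------------------------------------
# walking intervals and cycle slicing

def extract_walking_intervals(
    recording: ImuRecording,
    tug_phases: TugPhases | None = None,
    ic_left: np.ndarray | None = None,
) -> list[tuple[int, int]]:
    """Half-open walking intervals of one trial.

    TUG: the two walking phases between the sub-phase bursts.  10MWT: one
    interval spanning the trial with the first and last detected left gait
    cycle dropped (``ic_left`` must then be supplied).
    """
    if recording.trial_type == TRIAL_TUG:
        if tug_phases is None:
            raise ValueError("TUG trial requires tug_phases")
        return [tug_phases.walk1, tug_phases.walk2]
    if ic_left is None:
        raise ValueError("10MWT trial requires detected left ICs")
    ic_left = np.asarray(ic_left)
    n_cycles = ic_left.size - 1
    if n_cycles < 3:
        raise ValueError(
            f"10MWT needs >= 3 detected gait cycles, found {max(n_cycles, 0)}"
        )
    return [(int(ic_left[1]), int(ic_left[-2]))]


def extract_gait_cycles(
    recording: ImuRecording,
    intervals: list[tuple[int, int]],
    ics: np.ndarray,
    label: str,
    side: str = "left",
) -> list[GaitCycleWindow]:
    """One window per consecutive same-side IC pair inside one interval."""
    stacked = recording.stacked()
    ics = np.asarray(ics)
    windows = []
    for (lo, hi) in intervals:
        inside = ics[(ics >= lo) & (ics <= hi)]
        for s, e in zip(inside[:-1], inside[1:]):
            windows.append(
                GaitCycleWindow(
                    subject_id=recording.subject_id,
                    trial_type=recording.trial_type,
                    trial_index=recording.trial_index,
                    side=side,
                    start=int(s),
                    end=int(e),
                    data=stacked[s:e].copy(),
                    label=label,
                ).validate()
            )
    return windows


def segment_recording(
    recording: ImuRecording,
    label: str,
    side: str = "left",
    ic_params: IcParams | None = None,
    tug_threshold: float = 0.1,
) -> list[GaitCycleWindow]:
    """Full per-trial pipeline: filter, find events, slice gait cycles."""
    filtered = highpass_acceleration(recording)
    ankle = filtered.data[f"{side}_ankle"]
    ics = detect_initial_contacts(ankle, filtered.sample_rate_hz, ic_params)
    if recording.trial_type == TRIAL_TUG:
        phases = segment_tug_phases(filtered.data["lower_back"],
                                    filtered.sample_rate_hz, tug_threshold)
        intervals = extract_walking_intervals(filtered, tug_phases=phases)
    else:
        intervals = extract_walking_intervals(filtered, ic_left=ics)
    return extract_gait_cycles(filtered, intervals, ics, label, side)


def segment_subject(
    recordings: list[ImuRecording],
    label: str,
    side: str = "left",
    ic_params: IcParams | None = None,
) -> dict[tuple[str, int], list[GaitCycleWindow]]:
    """Segment every trial of one subject; windows keyed by trial."""
    return {
        rec.key(): segment_recording(rec, label, side, ic_params)
        for rec in recordings
    }
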