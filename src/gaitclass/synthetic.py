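"""Synthetic 10MWT / TUG cohort generator with ground-truth gait events.

The generator is a test harness, not a biomechanical simulator: walking is a
per-channel sum of the first four harmonics of the gait fundamental, with a
half-sine impact transient on the ankle accelerometers at each initial
contact (IC), Gaussian sensor noise everywhere, and raised-cosine
angular-velocity bursts marking the TUG sit-to-stand, turn and stand-to-sit
sub-phases.  Every event the downstream segmentation has to find is placed
at a known sample index and returned as :class:`~gaitclass.core.GroundTruth`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    CHANNELS,
    GroundTruth,
    ImuRecording,
    LABELS,
    LABEL_NA,
    LABEL_WA,
    N_CHANNELS,
    SITES,
    TRIAL_10MWT,
    TRIAL_TUG,
    TrialTruth,
    TugPhases,
    site_channel_slice,
)

# ---------------------------------------------------------------------------
# configuration

@dataclass
class ClassParams:
    """Signal statistics of one class (WA or NA)."""

    cycle_duration_s: tuple[float, float] = (1.1, 0.06)  # subject-level (mean, sd)
    step_amplitude_scale: float = 1.0
    arm_swing_scale: float = 1.0
    cycle_variability_s: float = 0.02  # per-cycle duration jitter sd
    sensor_noise_acc_g: float = 0.02
    sensor_noise_gyr_dps: float = 1.5


@dataclass
class CohortConfig:
    n_wa: int = 26
    n_na: int = 14
    seed: int = 0
    wa: ClassParams = field(default_factory=ClassParams)
    na: ClassParams = field(
        default_factory=lambda: ClassParams(
            cycle_duration_s=(1.45, 0.09),
            step_amplitude_scale=0.7,
            arm_swing_scale=0.35,
            cycle_variability_s=0.045,
        )
    )
    sample_rate_hz: float = 120.0
    mwt_n_cycles: int = 12        # left gait cycles per 10MWT trial
    tug_walk_cycles: tuple[int, int] = (5, 4)
    missing_tug_fraction: float = 0.05

    def validate(self) -> "CohortConfig":
        if self.n_wa + self.n_na < 2:
            raise ValueError("cohort must contain at least 2 subjects")
        if self.n_wa < 0 or self.n_na < 0:
            raise ValueError("group sizes must be nonnegative")
        for params in (self.wa, self.na):
            if min(
                params.cycle_duration_s[0],
                params.step_amplitude_scale,
                params.arm_swing_scale,
            ) <= 0:
                raise ValueError("class scales and durations must be positive")
        if not 0.0 <= self.missing_tug_fraction <= 1.0:
            raise ValueError("missing_tug_fraction must be in [0, 1]")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        if self.mwt_n_cycles < 1 or min(self.tug_walk_cycles) < 1:
            raise ValueError("trial lengths must be positive")
        return self

    def params_for(self, label: str) -> ClassParams:
        if label == LABEL_WA:
            return self.wa
        if label == LABEL_NA:
            return self.na
        raise ValueError(f"unknown class label {label!r}")

    @classmethod
    def desk_scale(cls, n_wa: int, n_na: int, seed: int = 0) -> "CohortConfig":
        """Small, fast cohort for CPU-bound end-to-end runs.

        Lower sampling rate and shorter trials shrink both segmentation and
        model-training cost; class statistics are unchanged.
        """
        return cls(
            n_wa=n_wa,
            n_na=n_na,
            seed=seed,
            sample_rate_hz=40.0,
            mwt_n_cycles=5,
            tug_walk_cycles=(4, 3),
            missing_tug_fraction=0.0,
        )


# ---------------------------------------------------------------------------
# per-site signal templates

# Peak harmonic amplitude per site: (acc in g, gyro in deg/s) per axis.
_SITE_AMPLITUDE: dict[str, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    "chest":       ((0.10, 0.06, 0.12), (8.0, 6.0, 5.0)),
    "lower_back":  ((0.12, 0.08, 0.15), (12.0, 5.0, 4.0)),
    "left_wrist":  ((0.25, 0.12, 0.20), (40.0, 25.0, 18.0)),
    "right_wrist": ((0.25, 0.12, 0.20), (40.0, 25.0, 18.0)),
    "left_thigh":  ((0.28, 0.10, 0.25), (60.0, 30.0, 15.0)),
    "right_thigh": ((0.28, 0.10, 0.25), (60.0, 30.0, 15.0)),
    "left_ankle":  ((0.40, 0.15, 0.45), (90.0, 40.0, 20.0)),
    "right_ankle": ((0.40, 0.15, 0.45), (90.0, 40.0, 20.0)),
}

_HARMONIC_WEIGHTS = np.array([1.0, 0.5, 0.25, 0.12])
_HARMONICS = np.arange(1, 5)

# Fixed per-(site, channel, harmonic) phase table; deterministic constants.
_PHASE_TABLE = np.random.default_rng(20240526).uniform(
    0.0, 2.0 * math.pi, size=(len(SITES), len(CHANNELS), len(_HARMONICS))
)

_IC_PULSE_WIDTH_S = 0.08
_IC_PULSE_ACC_Z_G = 1.0
_IC_PULSE_ACC_X_G = 0.4

_TAPER_S = 0.25
_WALK_LEAD_S = 0.3

# Raised-cosine bursts marking TUG sub-phases (amplitudes in deg/s).
_PITCH_BURST_DPS = 100.0
_YAW_BURST_DPS = 120.0
_SIT_TO_STAND_S = 1.5
_TURN_S = 2.0
# fraction of the burst width at which the pulse crosses 0.1 x its peak
_BURST_EDGE_FRACTION = math.acos(0.8) / (2.0 * math.pi)

_PITCH_BURST_WEIGHT = {
    "chest": 0.8, "lower_back": 1.0, "left_wrist": 0.1, "right_wrist": 0.1,
    "left_thigh": 0.6, "right_thigh": 0.6, "left_ankle": 0.1, "right_ankle": 0.1,
}
_YAW_BURST_WEIGHT = {
    "chest": 0.9, "lower_back": 1.0, "left_wrist": 0.5, "right_wrist": 0.5,
    "left_thigh": 0.5, "right_thigh": 0.5, "left_ankle": 0.5, "right_ankle": 0.5,
}


def _channel_amplitudes(params: ClassParams, subject_gain: float) -> np.ndarray:
    """(48,) peak amplitude per channel after class/subject scaling."""
    amps = np.empty(N_CHANNELS)
    for i, site in enumerate(SITES):
        acc, gyr = _SITE_AMPLITUDE[site]
        scale = params.step_amplitude_scale * subject_gain
        if site.endswith("wrist"):
            scale *= params.arm_swing_scale / params.step_amplitude_scale
        sl = site_channel_slice(site)
        amps[sl.start:sl.start + 3] = np.asarray(acc) * scale
        amps[sl.start + 3:sl.stop] = np.asarray(gyr) * scale
    return amps


def _add_noise(rng: np.random.Generator, sig: np.ndarray, params: ClassParams) -> None:
    n = sig.shape[0]
    for i in range(len(SITES)):
        base = i * len(CHANNELS)
        sig[:, base:base + 3] += rng.normal(0.0, params.sensor_noise_acc_g, (n, 3))
        sig[:, base + 3:base + 6] += rng.normal(0.0, params.sensor_noise_gyr_dps, (n, 3))


def _taper(n: int, fs: float) -> np.ndarray:
    """Cosine ramp-in/out window so segment joins are continuous."""
    w = np.ones(n)
    k = min(int(round(_TAPER_S * fs)), n // 2)
    if k > 0:
        ramp = 0.5 * (1.0 - np.cos(np.linspace(0.0, math.pi, k)))
        w[:k] = ramp
        w[-k:] = ramp[::-1]
    return w


def _half_sine_pulse(sig: np.ndarray, t_event: float, fs: float, col: int,
                     amp: float) -> None:
    n = sig.shape[0]
    width = max(int(round(_IC_PULSE_WIDTH_S * fs)), 2)
    start = int(round(t_event * fs))
    idx = np.arange(start, min(start + width, n))
    if idx.size:
        sig[idx, col] += amp * np.sin(math.pi * (idx - start) / width)


def _walking_segment(
    rng: np.random.Generator,
    n_cycles: int,
    cycle_s: float,
    params: ClassParams,
    subject_gain: float,
    fs: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build one walking bout; returns (signal, left IC idx, right IC idx)."""
    durations = cycle_s + rng.normal(0.0, params.cycle_variability_s, n_cycles)
    durations = np.clip(durations, 0.4 * cycle_s, None)
    ic_left_t = _WALK_LEAD_S + np.concatenate([[0.0], np.cumsum(durations)])
    ic_right_t = ic_left_t[:-1] + durations / 2.0
    total_s = ic_left_t[-1] + _WALK_LEAD_S
    n = int(round(total_s * fs)) + 1
    t = np.arange(n) / fs

    # piecewise-linear gait phase (in cycles) between consecutive left ICs
    phase = np.interp(t, ic_left_t, np.arange(n_cycles + 1))

    amps = _channel_amplitudes(params, subject_gain)
    harm = np.sin(
        2.0 * math.pi * _HARMONICS[None, None, :] * phase[:, None, None]
        + _PHASE_TABLE.reshape(1, N_CHANNELS, len(_HARMONICS))
    )  # (n, 48, 4)
    sig = (harm * _HARMONIC_WEIGHTS).sum(axis=2)
    sig /= _HARMONIC_WEIGHTS.sum()
    sig *= amps[None, :]

    # antiphase for right-side limbs: flip the fundamental's sign
    for site in ("right_wrist", "right_thigh", "right_ankle"):
        sl = site_channel_slice(site)
        flip = (harm[:, sl, 0] * -2.0 * _HARMONIC_WEIGHTS[0]) / _HARMONIC_WEIGHTS.sum()
        sig[:, sl] += flip * amps[None, sl]

    sig *= _taper(n, fs)[:, None]

    pulse_amp = params.step_amplitude_scale * subject_gain
    for side, ic_times in (("left", ic_left_t), ("right", ic_right_t)):
        sl = site_channel_slice(f"{side}_ankle")
        for t_ic in ic_times:
            _half_sine_pulse(sig, t_ic, fs, sl.start + 2, _IC_PULSE_ACC_Z_G * pulse_amp)
            _half_sine_pulse(sig, t_ic, fs, sl.start + 0, _IC_PULSE_ACC_X_G * pulse_amp)

    _add_noise(rng, sig, params)
    ic_left = np.round(ic_left_t * fs).astype(int)
    ic_right = np.round(ic_right_t * fs).astype(int)
    return sig, ic_left, ic_right


def _still_segment(rng: np.random.Generator, dur_s: float, params: ClassParams,
                   fs: float) -> np.ndarray:
    n = max(int(round(dur_s * fs)), 1)
    t = np.arange(n) / fs
    sig = np.zeros((n, N_CHANNELS))
    sway = 0.02 * np.sin(2.0 * math.pi * 0.3 * t)
    for site in ("chest", "lower_back"):
        sig[:, site_channel_slice(site).start + 0] += sway
    _add_noise(rng, sig, params)
    return sig


def _burst_segment(
    rng: np.random.Generator,
    dur_s: float,
    channel: str,
    amp: float,
    weights: dict[str, float],
    params: ClassParams,
    fs: float,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Raised-cosine angular-velocity burst; returns (signal, |x|>=0.1 peak extent)."""
    n = max(int(round(dur_s * fs)), 4)
    t = np.arange(n) / fs
    pulse = 0.5 * (1.0 - np.cos(2.0 * math.pi * np.clip(t / dur_s, 0.0, 1.0)))
    col = CHANNELS.index(channel)
    sig = np.zeros((n, N_CHANNELS))
    for site, w in weights.items():
        sig[:, site_channel_slice(site).start + col] += amp * w * pulse
    _add_noise(rng, sig, params)
    start = int(round(_BURST_EDGE_FRACTION * dur_s * fs))
    end = int(round((1.0 - _BURST_EDGE_FRACTION) * dur_s * fs))
    return sig, (start, end)


def _to_recording(subject_id: str, trial_type: str, trial_index: int,
                  fs: float, sig: np.ndarray) -> ImuRecording:
    data = {site: np.ascontiguousarray(sig[:, site_channel_slice(site)])
            for site in SITES}
    return ImuRecording(
        subject_id=subject_id,
        trial_type=trial_type,
        trial_index=trial_index,
        sample_rate_hz=fs,
        data=data,
    ).validate()


# ---------------------------------------------------------------------------
# public API

@dataclass
class CohortSubject:
    subject_id: str
    label: str
    recordings: list[ImuRecording]
    truth: GroundTruth


def generate_subject(
    class_label: str,
    config: CohortConfig,
    seed,
    subject_id: str = "S000",
) -> tuple[list[ImuRecording], GroundTruth]:
    """Generate one subject's trials (2 x 10MWT, 2 x TUG unless missing).

    ``seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    if class_label not in LABELS:
        raise ValueError(f"unknown class label {class_label!r}")
    config.validate()
    params = config.params_for(class_label)
    rng = np.random.default_rng(seed)
    fs = config.sample_rate_hz

    mean, sd = params.cycle_duration_s
    cycle_s = max(rng.normal(mean, sd), 0.4 * mean)
    subject_gain = max(1.0 + rng.normal(0.0, 0.05), 0.5)
    has_tug = rng.random() >= config.missing_tug_fraction

    recordings: list[ImuRecording] = []
    truth = GroundTruth(class_label=class_label)

    for trial_index in (1, 2):
        pre = _still_segment(rng, 1.0, params, fs)
        walk, ic_l, ic_r = _walking_segment(
            rng, config.mwt_n_cycles, cycle_s, params, subject_gain, fs
        )
        post = _still_segment(rng, 1.0, params, fs)
        sig = np.vstack([pre, walk, post])
        off = pre.shape[0]
        rec = _to_recording(subject_id, TRIAL_10MWT, trial_index, fs, sig)
        recordings.append(rec)
        truth.trials[rec.key()] = TrialTruth(
            ic_left=ic_l + off, ic_right=ic_r + off
        ).validate(rec.n_samples)

    if has_tug:
        for trial_index in (1, 2):
            rec, trial_truth = _generate_tug(
                rng, subject_id, trial_index, cycle_s, params, subject_gain, config
            )
            recordings.append(rec)
            truth.trials[rec.key()] = trial_truth

    return recordings, truth


def _generate_tug(rng, subject_id, trial_index, cycle_s, params, subject_gain,
                  config: CohortConfig):
    fs = config.sample_rate_hz
    n1, n2 = config.tug_walk_cycles

    segs: list[np.ndarray] = []
    marks: dict[str, tuple[int, int]] = {}
    ic_left_all: list[np.ndarray] = []
    ic_right_all: list[np.ndarray] = []

    def push(seg: np.ndarray) -> int:
        offset = sum(s.shape[0] for s in segs)
        segs.append(seg)
        return offset

    push(_still_segment(rng, 0.8, params, fs))

    seg, extent = _burst_segment(rng, _SIT_TO_STAND_S, "gyr_pitch",
                                 _PITCH_BURST_DPS, _PITCH_BURST_WEIGHT, params, fs)
    off = push(seg)
    marks["sit_to_stand"] = (off + extent[0], off + extent[1])

    for phase_name, n_cycles in (("walk1", n1), ("walk2", n2)):
        seg, ic_l, ic_r = _walking_segment(rng, n_cycles, cycle_s, params,
                                           subject_gain, fs)
        off = push(seg)
        ic_left_all.append(ic_l + off)
        ic_right_all.append(ic_r + off)
        seg, extent = _burst_segment(rng, _TURN_S, "gyr_yaw", _YAW_BURST_DPS,
                                     _YAW_BURST_WEIGHT, params, fs)
        off = push(seg)
        marks["turn1" if phase_name == "walk1" else "turn2"] = (
            off + extent[0], off + extent[1]
        )

    push(_still_segment(rng, 0.2, params, fs))
    seg, extent = _burst_segment(rng, _SIT_TO_STAND_S, "gyr_pitch",
                                 -_PITCH_BURST_DPS, _PITCH_BURST_WEIGHT, params, fs)
    off = push(seg)
    marks["stand_to_sit"] = (off + extent[0], off + extent[1])
    push(_still_segment(rng, 0.8, params, fs))

    sig = np.vstack(segs)
    phases = TugPhases(
        sit_to_stand=marks["sit_to_stand"],
        walk1=(marks["sit_to_stand"][1], marks["turn1"][0]),
        turn1=marks["turn1"],
        walk2=(marks["turn1"][1], marks["turn2"][0]),
        turn2=marks["turn2"],
        stand_to_sit=marks["stand_to_sit"],
    ).validate()
    rec = _to_recording(subject_id, TRIAL_TUG, trial_index, fs, sig)
    trial_truth = TrialTruth(
        ic_left=np.concatenate(ic_left_all),
        ic_right=np.concatenate(ic_right_all),
        tug_phases=phases,
    ).validate(rec.n_samples)
    return rec, trial_truth


def generate_cohort(config: CohortConfig) -> list[CohortSubject]:
    """Generate ``n_wa + n_na`` subjects with deterministic per-subject seeds."""
    config.validate()
    labels = [LABEL_WA] * config.n_wa + [LABEL_NA] * config.n_na
    children = np.random.SeedSequence(config.seed).spawn(len(labels))
    cohort = []
    for i, (label, child) in enumerate(zip(labels, children)):
        subject_id = f"S{i + 1:03d}"
        recordings, truth = generate_subject(label, config, child, subject_id)
        cohort.append(CohortSubject(subject_id, label, recordings, truth))
    return cohort


# ---------------------------------------------------------------------------
# on-disk format

CSV_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyr_roll", "gyr_pitch", "gyr_yaw"]
MANIFEST_NAME = "manifest.yaml"
TRUTH_NAME = "ground_truth.json"


def write_cohort(cohort: list[CohortSubject], directory) -> Path:
    """Write one CSV per sensor per trial plus a YAML manifest.

    Returns the manifest path.  TUG trials a subject is missing are listed
    in the manifest with ``present: false`` so readers can tell "absent by
    design" from "file lost".
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"sample_rate_hz": None, "subjects": []}
    truth_doc: dict = {}

    for subject in cohort:
        entry = {"id": subject.subject_id, "label": subject.label, "trials": []}
        present = {rec.key() for rec in subject.recordings}
        for rec in subject.recordings:
            manifest["sample_rate_hz"] = rec.sample_rate_hz
            rel = f"{subject.subject_id}/{rec.trial_type}_{rec.trial_index}"
            trial_dir = directory / rel
            trial_dir.mkdir(parents=True, exist_ok=True)
            t = np.arange(rec.n_samples) / rec.sample_rate_hz
            for site in SITES:
                frame = pd.DataFrame(
                    np.column_stack([t, rec.data[site]]), columns=CSV_COLUMNS
                )
                frame.to_csv(trial_dir / f"{site}.csv", index=False)
            entry["trials"].append(
                {"trial_type": rec.trial_type, "trial_index": rec.trial_index,
                 "dir": rel, "present": True}
            )
        for trial_index in (1, 2):
            if (TRIAL_TUG, trial_index) not in present:
                entry["trials"].append(
                    {"trial_type": TRIAL_TUG, "trial_index": trial_index,
                     "dir": None, "present": False}
                )
        manifest["subjects"].append(entry)
        truth_doc[subject.subject_id] = _truth_to_json(subject.truth)

    manifest_path = directory / MANIFEST_NAME
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(directory / TRUTH_NAME, "w") as fh:
        json.dump(truth_doc, fh, indent=1)
    return manifest_path


def _truth_to_json(truth: GroundTruth) -> dict:
    doc = {"class_label": truth.class_label, "trials": {}}
    for (trial_type, trial_index), tt in truth.trials.items():
        item = {
            "ic_left": np.asarray(tt.ic_left).tolist(),
            "ic_right": np.asarray(tt.ic_right).tolist(),
        }
        if tt.tug_phases is not None:
            item["tug_phases"] = {
                name: list(interval)
                for name, interval in asdict(tt.tug_phases).items()
            }
        doc["trials"][f"{trial_type}_{trial_index}"] = item
    return doc


def read_ground_truth(directory) -> dict[str, GroundTruth]:
    """Load the ground-truth sidecar written by :func:`write_cohort`."""
    with open(Path(directory) / TRUTH_NAME) as fh:
        doc = json.load(fh)
    out = {}
    for subject_id, item in doc.items():
        truth = GroundTruth(class_label=item["class_label"])
        for key, tt in item["trials"].items():
            trial_type, trial_index = key.rsplit("_", 1)
            phases = None
            if "tug_phases" in tt:
                phases = TugPhases(**{k: tuple(v) for k, v in tt["tug_phases"].items()})
            truth.trials[(trial_type, int(trial_index))] = TrialTruth(
                ic_left=np.asarray(tt["ic_left"], dtype=int),
                ic_right=np.asarray(tt["ic_right"], dtype=int),
                tug_phases=phases,
            )
        out[subject_id] = truth
    return out
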