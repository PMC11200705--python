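"""Gait-cycle windows -> fixed-size normalized model inputs.

Normalization is per subject-trial and per modality/axis channel group: each
of the 6 groups (3 acceleration axes, 3 angular-velocity axes) is divided by
the maximum absolute value that group attains across all 8 sensors and all
walking-phase samples of the trial, then halved and shifted so the baseline
sits at 0.5.  Shorter-than-maximum cycles are padded with the constant 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    GaitCycleWindow,
    N_CHANNELS,
    N_CHANNELS_PER_SITE,
    NormalizedSample,
    SITES,
    channel_group_indices,
    site_channel_slice,
)

PAD_VALUE = 0.5
DEFAULT_LENGTH_MAX = 276


def normalize_windows(windows: list[GaitCycleWindow]) -> list[GaitCycleWindow]:
    """Normalize one subject-trial's windows into [0, 1] with baseline 0.5.

    The denominator of each channel group is the group's maximum absolute
    value over every window of the trial, so within the trial either the
    minimum 0 or the maximum 1 is attained depending on the sign of the
    extremum.
    """
    if not windows:
        raise ValueError("cannot normalize an empty window set")
    stacked = np.vstack([w.data for w in windows])
    denominators = np.empty(N_CHANNELS_PER_SITE)
    for axis in range(N_CHANNELS_PER_SITE):
        group = np.abs(stacked[:, channel_group_indices(axis)]).max()
        if group == 0.0:
            raise ValueError(f"all-zero channel group {axis} (denominator 0)")
        denominators[axis] = group
    per_channel = np.tile(denominators, len(SITES))
    return [
        replace(w, data=w.data / per_channel / 2.0 + PAD_VALUE) for w in windows
    ]


def pad_window(window: GaitCycleWindow, length_max: int = DEFAULT_LENGTH_MAX) -> NormalizedSample:
    """Pad a normalized window to ``length_max`` with the constant 0.5.

    Windows longer than ``length_max`` are rejected rather than truncated.
    """
    n = window.data.shape[0]
    if n > length_max:
        raise ValueError(f"window length {n} exceeds length_max {length_max}")
    matrix = np.full((length_max, N_CHANNELS), PAD_VALUE)
    matrix[:n] = window.data
    return NormalizedSample(
        matrix=matrix,
        subject_id=window.subject_id,
        label=window.label,
        valid_length=n,
    ).validate()


def augment(
    samples: list[NormalizedSample],
    n_copies: int = 4,
    noise_half_width: float = 0.1,
    seed=0,
    clip: bool = True,
) -> list[NormalizedSample]:
    """Originals plus ``n_copies`` uniformly jittered copies of each sample.

    Noise is i.i.d. uniform on ``[-noise_half_width, noise_half_width]``
    added to every value; noisy values are clipped back to [0, 1] unless
    ``clip`` is disabled.
    """
    if n_copies < 0:
        raise ValueError("n_copies must be nonnegative")
    rng = np.random.default_rng(seed)
    out = list(samples)
    for _ in range(n_copies):
        for s in samples:
            noisy = s.matrix + rng.uniform(
                -noise_half_width, noise_half_width, s.matrix.shape
            )
            if clip:
                noisy = np.clip(noisy, 0.0, 1.0)
            out.append(replace(s, matrix=noisy))
    return out


def mask_sensors(sample: NormalizedSample, excluded_sites) -> NormalizedSample:
    """Replace every value of the excluded sites' channels with 0.5."""
    excluded = list(excluded_sites)
    for site in excluded:
        if site not in SITES:
            raise ValueError(f"unknown sensor site {site!r}")
    if not excluded:
        return sample
    matrix = sample.matrix.copy()
    for site in excluded:
        matrix[:, site_channel_slice(site)] = PAD_VALUE
    return replace(sample, matrix=matrix)


def _balance(samples: list[NormalizedSample], rng: np.random.Generator) -> list[NormalizedSample]:
    """Equalize label counts by random undersampling of the majority label."""
    by_label: dict[str, list[NormalizedSample]] = {}
    for s in samples:
        by_label.setdefault(s.label, []).append(s)
    if len(by_label) < 2:
        raise ValueError("cannot balance a single-class sample set")
    n_min = min(len(v) for v in by_label.values())
    out = []
    for label in sorted(by_label):
        group = by_label[label]
        keep = rng.choice(len(group), size=n_min, replace=False)
        out.extend(group[i] for i in sorted(keep))
    return out


def assemble_fold(
    samples: list[NormalizedSample],
    held_out_subject: str,
    val_fraction: float = 0.1,
    balance: bool = True,
    seed=0,
    n_copies: int = 4,
    noise_half_width: float = 0.1,
    augment_train: bool = True,
    augment_before_split: bool = False,
) -> tuple[list[NormalizedSample], list[NormalizedSample], list[NormalizedSample]]:
    """One leave-one-subject-out fold: (train, val, test).

    The held-out subject's samples form the test set and are never
    augmented.  The remaining samples are label-balanced by undersampling,
    split ``1 - val_fraction`` / ``val_fraction`` into train/val, and the
    train portion is noise-augmented.  ``augment_before_split`` instead
    augments the whole training pool before splitting, which lets noisy
    copies of one cycle land on both sides of the train/val split
    (leakage-prone; off by default).
    """
    rng = np.random.default_rng(seed)
    test = [s for s in samples if s.subject_id == held_out_subject]
    if not test:
        raise ValueError(f"held-out subject {held_out_subject!r} has no samples")
    rest = [s for s in samples if s.subject_id != held_out_subject]
    if len({s.label for s in rest}) < 2:
        raise ValueError("remaining cohort must contain both labels")

    if balance:
        rest = _balance(rest, rng)
    if augment_before_split and augment_train:
        rest = augment(rest, n_copies, noise_half_width, seed=rng.integers(2**32))

    order = rng.permutation(len(rest))
    n_val = int(round(val_fraction * len(rest)))
    val = [rest[i] for i in order[:n_val]]
    train = [rest[i] for i in order[n_val:]]
    if not augment_before_split and augment_train:
        train = augment(train, n_copies, noise_half_width, seed=rng.integers(2**32))
    return train, val, test


def build_subject_samples(
    trial_windows: dict[tuple[str, int], list[GaitCycleWindow]],
    length_max: int,
) -> list[NormalizedSample]:
    """Normalize each trial's windows, pad, and pool across trials."""
    samples = []
    for key in sorted(trial_windows):
        windows = trial_windows[key]
        if not windows:
            continue
        for w in normalize_windows(windows):
            samples.append(pad_window(w, length_max))
    return samples


def save_samples(samples: list[NormalizedSample], path) -> None:
    """Persist normalized samples to an HDF5 container.

    Layout: ``matrices (n, length_max, 48)`` plus per-sample ``subject_id``,
    ``label`` and ``valid_length`` datasets; the canonical channel order is
    recorded as a file attribute.
    """
    import h5py

    from .core import CHANNELS, SITES

    if not samples:
        raise ValueError("no samples to save")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("matrices", data=np.stack([s.matrix for s in samples]))
        str_dt = h5py.string_dtype()
        fh.create_dataset("subject_id", data=[s.subject_id for s in samples], dtype=str_dt)
        fh.create_dataset("label", data=[s.label for s in samples], dtype=str_dt)
        fh.create_dataset("valid_length", data=[s.valid_length for s in samples])
        fh.attrs["channel_order"] = [
            f"{site}/{ch}" for site in SITES for ch in CHANNELS
        ]
        fh.attrs["length_max"] = samples[0].matrix.shape[0]


def load_samples(path) -> list[NormalizedSample]:
    import h5py

    with h5py.File(path, "r") as fh:
        matrices = fh["matrices"][...]
        subject_ids = [s.decode() for s in fh["subject_id"][...]]
        labels = [s.decode() for s in fh["label"][...]]
        valid = fh["valid_length"][...]
    return [
        NormalizedSample(matrix=m, subject_id=sid, label=lab, valid_length=int(v)).validate()
        for m, sid, lab, v in zip(matrices, subject_ids, labels, valid)
    ]


def samples_to_arrays(samples: list[NormalizedSample], dtype=np.float32):
    """Stack samples into model-ready ``(n, T, 48)`` inputs and label indices."""
    from .core import LABEL_TO_INDEX

    x = np.stack([s.matrix for s in samples]).astype(dtype)
    y = np.array([LABEL_TO_INDEX[s.label] for s in samples], dtype=np.int64)
    return x, y
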