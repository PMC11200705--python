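"""End-to-end glue: recordings -> segmented windows -> normalized samples."""

from __future__ import annotations

import numpy as np

from .dataset import DEFAULT_LENGTH_MAX, build_subject_samples
from .evaluation import SubjectSamples
from .segmentation import IcParams, segment_subject


def cohort_windows(subjects, side: str = "left", ic_params: IcParams | None = None):
    """Segment every subject; returns ``{subject_id: (label, trial_windows)}``.

    ``subjects`` is any sequence of objects with ``subject_id``, ``label``
    and ``recordings`` attributes (generated cohorts and cohorts read from
    disk both qualify).  Subjects with missing trials simply contribute
    fewer windows; nobody is dropped.
    """
    out = {}
    for subject in subjects:
        out[subject.subject_id] = (
            subject.label,
            segment_subject(subject.recordings, subject.label, side, ic_params),
        )
    return out


def cohort_to_samples(
    subjects,
    length_max: int | None = None,
    side: str = "left",
    ic_params: IcParams | None = None,
) -> list[SubjectSamples]:
    """Full preprocessing for a cohort, ready for LOOCV.

    When ``length_max`` is None it is set to the longest observed cycle in
    the cohort (the study-cohort equivalent of the 276-sample default in
    :data:`gaitclass.dataset.DEFAULT_LENGTH_MAX`).
    """
    windows = cohort_windows(subjects, side, ic_params)
    if length_max is None:
        lengths = [
            w.length
            for _, trials in windows.values()
            for ws in trials.values()
            for w in ws
        ]
        if not lengths:
            raise ValueError("no gait cycles found in cohort")
        length_max = int(max(lengths))
    cohort = []
    for subject_id in sorted(windows):
        label, trials = windows[subject_id]
        samples = build_subject_samples(trials, length_max)
        if samples:
            cohort.append(SubjectSamples(subject_id, label, samples))
    return cohort


def observed_length_max(cohort: list[SubjectSamples]) -> int:
    return int(max(np.max([s.valid_length for s in subj.samples]) for subj in cohort))
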