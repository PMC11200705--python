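"""Leave-one-subject-out evaluation, metrics, and the sensor-ablation sweep.

The headline numbers are cycle-pooled: every held-out subject's per-cycle
predictions from all folds are pooled into a single confusion matrix (NA is
the positive class), from which accuracy, sensitivity, and specificity are
computed.  Per-subject accuracy fractions are reported alongside.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    ConfusionMatrix,
    LABEL_NA,
    Metrics,
    NormalizedSample,
    SITES,
)
from .dataset import assemble_fold, mask_sensors, samples_to_arrays
from .model import ModelConfig, TrainConfig, build_model, predict, train


def compute_metrics(cm: ConfusionMatrix) -> Metrics:
    """Accuracy / sensitivity / specificity; zero denominators yield NaN."""
    cm.validate()

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return Metrics(
        accuracy=ratio(cm.tp + cm.tn, cm.total),
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
    )


@dataclass
class PredictionRecord:
    subject_id: str
    cycle_index: int
    truth: str
    predicted: str
    p_na: float


@dataclass
class LoocvResult:
    sensor_set: tuple[str, ...]
    confusion: ConfusionMatrix
    metrics: Metrics
    per_subject_accuracy: dict[str, float]
    predictions: list[PredictionRecord] = field(default_factory=list)
    n_models: int = 0

    @property
    def per_fold_accuracies(self) -> list[float]:
        return [self.per_subject_accuracy[s] for s in sorted(self.per_subject_accuracy)]


#: Named ablation subsets reported alongside the full set and the
#: leave-one-sensor-out screen.
NAMED_SUBSETS: dict[str, tuple[str, ...]] = {
    "five": ("right_ankle", "left_wrist", "right_wrist", "right_thigh", "chest"),
    "three": ("right_ankle", "left_wrist", "right_wrist"),
    "two_a": ("right_ankle", "left_wrist"),
    "two_b": ("right_ankle", "right_wrist"),
}


def sweep_subsets(spec: str = "full") -> list[tuple[str, ...]]:
    """Sensor subsets of an ablation sweep.

    ``"loo"``: the full set plus each leave-one-sensor-out subset;
    ``"named"``: the full set plus the four reported reduced subsets;
    ``"full"``: all of the above (13 LOOCV runs).
    """
    all_sites = tuple(SITES)
    loo = [tuple(s for s in SITES if s != excl) for excl in SITES]
    named = [tuple(v) for v in NAMED_SUBSETS.values()]
    if spec == "loo":
        return [all_sites] + loo
    if spec == "named":
        return [all_sites] + named
    if spec == "full":
        return [all_sites] + loo + named
    raise ValueError(f"unknown sweep spec {spec!r}")


@dataclass
class SubjectSamples:
    subject_id: str
    label: str
    samples: list[NormalizedSample]


def run_loocv(
    cohort: list[SubjectSamples],
    model_config: ModelConfig,
    train_config: TrainConfig,
    sensor_set: tuple[str, ...] | None = None,
    seed: int = 0,
    val_fraction: float = 0.1,
    n_copies: int = 4,
    balance: bool = True,
) -> LoocvResult:
    """One fold per subject: train on the rest, predict the held-out cycles.

    ``sensor_set`` restricts the model to those sites; all other sites'
    channels are replaced by the constant 0.5 in every fold's train,
    validation, and test inputs alike.  Per-fold seeds derive from ``seed``
    plus the fold index.
    """
    if len(cohort) < 2:
        raise ValueError("LOOCV needs at least 2 subjects")
    if len({s.label for s in cohort}) < 2:
        raise ValueError("cohort must contain both labels")
    sensor_set = tuple(SITES) if sensor_set is None else tuple(sensor_set)
    if not sensor_set:
        raise ValueError("sensor set must not be empty")
    excluded = tuple(s for s in SITES if s not in sensor_set)

    pool = [s for subj in cohort for s in subj.samples]
    pool = [mask_sensors(s, excluded) for s in pool]

    cm = ConfusionMatrix()
    per_subject: dict[str, float] = {}
    records: list[PredictionRecord] = []
    n_models = 0

    for fold_index, subject in enumerate(sorted(cohort, key=lambda s: s.subject_id)):
        fold_seed = seed + fold_index
        train_set, val_set, test_set = assemble_fold(
            pool,
            held_out_subject=subject.subject_id,
            val_fraction=val_fraction,
            balance=balance,
            seed=fold_seed,
            n_copies=n_copies,
        )
        train_ids = {s.subject_id for s in train_set} | {s.subject_id for s in val_set}
        assert subject.subject_id not in train_ids, "subject leakage across fold"

        x_tr, y_tr = samples_to_arrays(train_set)
        x_va, y_va = (samples_to_arrays(val_set) if val_set else (None, None))
        x_te, _ = samples_to_arrays(test_set)

        model = build_model(model_config, seed=fold_seed)
        train(model, x_tr, y_tr, train_config, x_va, y_va)
        n_models += 1

        probs, labels = predict(model, x_te)
        correct = 0
        for cycle_index, (sample, p, lab) in enumerate(zip(test_set, probs, labels)):
            cm.add(sample.label, lab)
            correct += int(lab == sample.label)
            records.append(
                PredictionRecord(subject.subject_id, cycle_index, sample.label,
                                 lab, float(p[1]))
            )
        per_subject[subject.subject_id] = correct / len(test_set)

    result = LoocvResult(
        sensor_set=sensor_set,
        confusion=cm,
        metrics=compute_metrics(cm),
        per_subject_accuracy=per_subject,
        predictions=records,
        n_models=n_models,
    )
    _check_metric_identity(result)
    return result


def _check_metric_identity(result: LoocvResult) -> None:
    """Pooled accuracy must equal the prevalence-weighted mean of
    sensitivity and specificity; cheap invariant asserted on every run."""
    cm = result.confusion
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    m = result.metrics
    if pos and neg:
        weighted = (pos * m.sensitivity + neg * m.specificity) / cm.total
        assert abs(weighted - m.accuracy) < 1e-12


def metrics_from_records(records: list[PredictionRecord]) -> Metrics:
    """Independent recount of the metrics from the raw prediction log."""
    cm = ConfusionMatrix()
    for r in records:
        cm.add(r.truth, r.predicted)
    return compute_metrics(cm)


def ablation_sweep(
    cohort: list[SubjectSamples],
    model_config: ModelConfig,
    train_config: TrainConfig,
    sweep: str = "full",
    seed: int = 0,
    **loocv_kwargs,
) -> list[LoocvResult]:
    """Run one LOOCV per sensor subset of the requested sweep."""
    return [
        run_loocv(cohort, model_config, train_config, sensor_set=subset,
                  seed=seed, **loocv_kwargs)
        for subset in sweep_subsets(sweep)
    ]


# ---------------------------------------------------------------------------
# reporting

def _subset_name(sensor_set: tuple[str, ...]) -> str:
    if set(sensor_set) == set(SITES):
        return "all_8"
    if len(sensor_set) == len(SITES) - 1:
        (missing,) = set(SITES) - set(sensor_set)
        return f"without_{missing}"
    return "+".join(sensor_set)


def report(results: list[LoocvResult], out_dir) -> list[Path]:
    """Write the metrics table, per-subject accuracies, prediction logs,
    and confusion-matrix figures for a list of ablation results."""
    if not results:
        raise ValueError("nothing to report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    table = out_dir / "metrics.csv"
    with open(table, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sensor_set", "accuracy", "sensitivity", "specificity"])
        for r in results:
            writer.writerow(
                [_subset_name(r.sensor_set), f"{r.metrics.accuracy:.6f}",
                 f"{r.metrics.sensitivity:.6f}", f"{r.metrics.specificity:.6f}"]
            )
    written.append(table)

    for r in results:
        name = _subset_name(r.sensor_set)
        per_subject = out_dir / f"per_subject_{name}.csv"
        with open(per_subject, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "accuracy"])
            for sid in sorted(r.per_subject_accuracy):
                writer.writerow([sid, f"{r.per_subject_accuracy[sid]:.6f}"])
        written.append(per_subject)

        log = out_dir / f"predictions_{name}.csv"
        with open(log, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["subject_id", "cycle_index", "truth", "predicted", "p_na"])
            for rec in r.predictions:
                writer.writerow([rec.subject_id, rec.cycle_index, rec.truth,
                                 rec.predicted, f"{rec.p_na:.6f}"])
        written.append(log)
        written.append(_confusion_figure(r, out_dir / f"confusion_{name}.png"))
    return written


def _confusion_figure(result: LoocvResult, path: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = result.confusion
    grid = np.array([[cm.tp, cm.fn], [cm.fp, cm.tn]])
    fig, ax = plt.subplots(figsize=(3.2, 3.0))
    ax.imshow(grid, cmap="Blues")
    for (i, j), v in np.ndenumerate(grid):
        ax.text(j, i, str(v), ha="center", va="center")
    ax.set_xticks([0, 1], [f"pred {LABEL_NA}", "pred WA"])
    ax.set_yticks([0, 1], [f"true {LABEL_NA}", "true WA"])
    ax.set_title(f"{_subset_name(result.sensor_set)}  acc={result.metrics.accuracy:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
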