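"""CPU-scale preset configurations used by the demo runs and acceptance checks.

The package defaults mirror the reference configuration (276 x 48 inputs,
d_model 48, 5 encoder blocks, 130 epochs at lr 1e-5).  The presets here are
reduced settings for single-CPU end-to-end runs on synthetic cohorts: same
architecture, smaller sizes, a learning rate that can move a freshly
initialized network within 20 epochs, and x3 instead of x5 augmentation.
"""

from __future__ import annotations

from .evaluation import LoocvResult, run_loocv
from .model import ModelConfig, TrainConfig
from .pipeline import cohort_to_samples
from .synthetic import CohortConfig, generate_cohort


def desk_model_config(seq_len: int) -> ModelConfig:
    return ModelConfig(seq_len=seq_len, d_model=24, n_blocks=2, n_heads=4,
                       ff_dim=48, dropout=0.1)


def desk_train_config(seed: int, epochs: int = 20) -> TrainConfig:
    return TrainConfig(epochs=epochs, batch_size=64, learning_rate=1.5e-3, seed=seed)


def tiny_model_config(seq_len: int) -> ModelConfig:
    """Smallest config that still exercises every layer; for smoke runs."""
    return ModelConfig(seq_len=seq_len, d_model=8, n_blocks=1, n_heads=2,
                       ff_dim=16, dropout=0.0)


def desk_loocv(
    seed: int,
    n_wa: int = 7,
    n_na: int = 5,
    sensor_set: tuple[str, ...] | None = None,
    epochs: int = 20,
    n_copies: int = 2,
) -> LoocvResult:
    """Generate a desk-scale cohort and run full LOOCV on it."""
    config = CohortConfig.desk_scale(n_wa=n_wa, n_na=n_na, seed=seed)
    samples = cohort_to_samples(generate_cohort(config))
    seq_len = samples[0].samples[0].matrix.shape[0]
    return run_loocv(
        samples,
        desk_model_config(seq_len),
        desk_train_config(seed, epochs=epochs),
        sensor_set=sensor_set,
        seed=seed,
        n_copies=n_copies,
    )
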