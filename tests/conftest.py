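import numpy as np
import pytest

from gaitclass.core import GaitCycleWindow, N_CHANNELS
from gaitclass.synthetic import CohortConfig, generate_subject


@pytest.fixture(scope="session")
def default_config() -> CohortConfig:
    # missing_tug_fraction pinned to 0 so every fixture subject has TUG trials
    return CohortConfig(missing_tug_fraction=0.0)


@pytest.fixture(scope="session")
def wa_subject(default_config):
    return generate_subject("WA", default_config, seed=1, subject_id="WA01")


@pytest.fixture(scope="session")
def na_subject(default_config):
    return generate_subject("NA", default_config, seed=1, subject_id="NA01")


def make_window(data: np.ndarray, subject_id="S001", label="WA",
                trial_type="10MWT", start=0) -> GaitCycleWindow:
    """Wrap a raw (n, 48) array into a valid window for dataset-level tests."""
    assert data.shape[1] == N_CHANNELS
    return GaitCycleWindow(
        subject_id=subject_id,
        trial_type=trial_type,
        trial_index=1,
        side="left",
        start=start,
        end=start + data.shape[0],
        data=data,
        label=label,
    ).validate()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
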