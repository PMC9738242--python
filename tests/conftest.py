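import numpy as np
import pytest

from wristbow import pipeline, synth


@pytest.fixture(scope="session")
def mini_preset():
    return pipeline.mini_preset()


@pytest.fixture(scope="session")
def mini_cohort(mini_preset):
    """A small effect cohort (16 HE + 14 PD, two 600-s day units at 32 Hz)."""
    cfg = mini_preset.cohort_config(master_seed=11, n_he=16, n_pd=14)
    return synth.generate_cohort(cfg)


@pytest.fixture(scope="session")
def mini_labels(mini_cohort):
    return pipeline.cohort_labels(mini_cohort)


@pytest.fixture(scope="session")
def mini_descriptors(mini_preset, mini_cohort):
    return pipeline.cohort_descriptors(mini_cohort, mini_preset.windows_s)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
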