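import numpy as np
import pytest

import hilofuse as hf


@pytest.fixture(scope="session")
def tiny_params():
    return hf.SimParams.tiny(seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return hf.generate_cohort(tiny_params)


@pytest.fixture(scope="session")
def tiny_cfg():
    return hf.EncoderConfig.tiny()


@pytest.fixture(scope="session")
def smoke_model(tiny_cohort, tiny_cfg):
    """A briefly trained fusion model shared by plumbing-level tests."""
    subset = tiny_cohort.records[:10] + tiny_cohort.records[-10:]
    model, history = hf.train(subset, tiny_cfg, hf.TrainConfig.smoke(epochs=3, seed=5))
    return model, history, subset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
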