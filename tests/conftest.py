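import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from csprad.phantom import CS_LABEL, NONCS_LABEL, PhantomConfig, make_lesion_sample
from csprad.preprocess import preprocess_sample
from csprad.quantize import QuantizedVolume


@pytest.fixture(scope="session")
def phantom_config():
    return PhantomConfig()


@pytest.fixture(scope="session")
def lesion_sample(phantom_config):
    rng = np.random.default_rng(42)
    return make_lesion_sample(phantom_config, CS_LABEL, "PZ", rng)


@pytest.fixture(scope="session")
def preprocessed_sample(lesion_sample):
    return preprocess_sample(lesion_sample)


def quantized_from_labels(labels, mask=None, n_levels=None):
    """Build a QuantizedVolume directly from a small integer label array."""
    labels = np.asarray(labels, dtype=np.int32)
    if mask is None:
        mask = labels > 0
    mask = np.asarray(mask, dtype=bool)
    labels = np.where(mask, labels, 0)
    if n_levels is None:
        n_levels = int(labels.max())
    return QuantizedVolume(labels=labels, mask=mask, n_levels=n_levels)


@pytest.fixture
def make_quantized():
    return quantized_from_labels
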