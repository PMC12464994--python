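import numpy as np
import pytest

from fluorodimer import (
    BiasParameters,
    MixingSpec,
    get_preset_table,
    simulate_sample_spectrum,
)


@pytest.fixture
def table_5fw():
    return get_preset_table("5FW-W63")


@pytest.fixture
def table_e14q():
    return get_preset_table("5FW-W63-E14Q")


@pytest.fixture
def one_to_three():
    """The reference 1:3 labeled:unlabeled mixture at 310 K."""
    return MixingSpec(labeled_ratio=0.25, incorporation_efficiency=1.0)


@pytest.fixture
def label_only_bias():
    """A label-bias-only heterodimer sample (dg_fw = 0.8 kcal/mol)."""
    return BiasParameters(dg_fw=0.8, dg_mut=0.0, label_on_mutant=True)


@pytest.fixture
def simulated_1to3(one_to_three, label_only_bias, table_5fw):
    """Noiseless 1:3 spectrum with the merged-B layout (three peaks)."""
    return simulate_sample_spectrum(
        one_to_three, label_only_bias, table_5fw, seed=0, noise_sigma=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
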