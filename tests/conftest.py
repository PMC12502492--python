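import warnings

import numpy as np
import pytest

from recaplab import synthgen

# umap-learn emits numba/sklearn deprecation chatter on import; keep test
# output readable without hiding our own warnings
warnings.filterwarnings("ignore", module="umap")
warnings.filterwarnings("ignore", module="numba")


@pytest.fixture(scope="session")
def hrp_image_snr8():
    """One proficient-regime 2 h field at the default SNR (8)."""
    return synthgen.gen_recap_image(synthgen.HRP_REGIME, "post2h", seed=11)


@pytest.fixture(scope="session")
def hrp_image_noiseless():
    return synthgen.gen_recap_image(synthgen.HRP_REGIME, "post2h", seed=5,
                                    noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """2 HRD + 2 HRP models, 3 conditions each, reduced field."""
    return synthgen.gen_recap_cohort(2, 2, seed=42, shape=(320, 320),
                                     nucleus_count=40)


@pytest.fixture(scope="session")
def paired_counts():
    spec = synthgen.PairedExpressionSpec(n_genes=800, n_pairs=8, seed=1)
    return synthgen.gen_paired_expression(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
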