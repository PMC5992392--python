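import logging

import numpy as np
import pytest
from hypothesis import settings

from mia.datasets import IndexRange, IntegratedDataset, MethodParams
from mia.simulate import SimulationConfig, generate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# the nonneg-split notice is expected all over the suite
logging.getLogger("mia.preprocess").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_bundle():
    """Low-noise simulated data at full default size (one per session)."""
    return generate(SimulationConfig(seed=7, noise_sd=0.25))


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Nearly noise-free bundle for exact recovery checks."""
    return generate(SimulationConfig(seed=11, noise_sd=1e-3))


@pytest.fixture
def three_block_dataset(rng):
    m, widths = 8, [5, 3, 4]
    n = sum(widths)
    data = rng.normal(size=(m, n))
    starts = np.cumsum([0] + widths)
    return IntegratedDataset(
        data=data,
        x_blocks=[IndexRange(int(a), int(b)) for a, b in zip(starts[:-1], starts[1:])],
        y_block=None,
        sample_labels=[f"s{i}" for i in range(m)],
        feature_labels=[f"f{j}" for j in range(n)],
        feature_types=["Gene", "miRNA", "Methylation"],
        params=MethodParams(n_modules=2, seed=1),
    )
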