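import numpy as np
import pytest

import hillbayes as hb


@pytest.fixture(scope="session")
def noiseless_dataset() -> hb.DoseResponseDataset:
    """12 exact Hill-curve points from (pIC50=6, Hill=1), three experiments."""
    spec = hb.GeneratorSpec(
        pic50=6.0, hill=1.0, sigma=0.0, n_experiments=3,
        concentrations=(0.05, 0.3, 1.0, 9.0), seed=0,
    )
    return hb.generate_dataset(spec)


@pytest.fixture(scope="session")
def fig9_dataset() -> hb.DoseResponseDataset:
    """16-experiment synthetic study dataset (logistic pIC50, log-logistic Hill)."""
    return hb.generate_dataset(hb.preset("fig9", seed=101))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
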