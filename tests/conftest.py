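import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from evspec import preprocessing, som, synthetic
from evspec.core import LabeledDataset, WavenumberAxis


@pytest.fixture(scope="session")
def axis():
    return WavenumberAxis()


@pytest.fixture(scope="session")
def noiseless_small_pair():
    """Noiseless (small, healthy) vs (small, cvd) dataset, 5 spectra each."""
    return synthetic.generate_dataset(
        {("small", "healthy"): 5, ("small", "cvd"): 5},
        synthetic.NOISELESS,
        seed=7,
        label_by="state",
    )


@pytest.fixture(scope="session")
def small_disease_run():
    """Preprocessed 40/40 small-EV healthy-vs-CVD dataset with a trained model.

    Shared across SOM, SOMDI and evaluation tests to keep the suite fast.
    """
    ds = synthetic.generate_dataset(
        {("small", "healthy"): 40, ("small", "cvd"): 40}, seed=11, label_by="state"
    )
    clean = preprocessing.preprocess_dataset(ds)
    result = som.train_test_evaluate(clean, som.SOMParams(seed=11), som.SplitSpec(seed=11))
    return clean, result
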