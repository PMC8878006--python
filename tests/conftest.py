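import numpy as np
import pandas as pd
import pytest

from crossmet.design_io import FeatureTable
from crossmet.synthetic import SyntheticSpec, generate_crossover


def make_table(values, raw=None):
    """Wrap a plain matrix in a FeatureTable with dummy m/z metadata."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    samples = [f"S{i + 1:03d}" for i in range(n)]
    features = [f"F{j + 1:03d}" for j in range(p)]
    meta = pd.DataFrame(
        {"mz": np.linspace(100, 900, p), "rt": np.linspace(1, 20, p),
         "polarity": "positive"},
        index=features,
    )
    if raw is None:
        raw = not (np.nanmin(values) < 0)
    return FeatureTable(pd.DataFrame(values, index=samples, columns=features),
                        meta, raw=raw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_study():
    """One full crossover realization at the default study conditions."""
    spec = SyntheticSpec(n_features=300, seed=7)
    return generate_crossover(spec) + (spec,)
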