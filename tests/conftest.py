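import numpy as np
import pytest

from cvbias.datasets import LabeledTable, SyntheticSpec, generate_radiomics_like, preprocess


@pytest.fixture
def imbalanced_table():
    """Preprocessed 80/20 radiomics-like table (balance 4, minority = label 1)."""
    spec = SyntheticSpec(
        n_samples=100, n_features=10, n_informative=2, effect_size=1.0,
        balance=4.0, seed=0,
    )
    return preprocess(generate_radiomics_like(spec))


@pytest.fixture
def balanced_table():
    spec = SyntheticSpec(
        n_samples=60, n_features=8, n_informative=2, effect_size=1.0,
        balance=1.0, seed=1,
    )
    return preprocess(generate_radiomics_like(spec))


def make_table(X, y):
    return LabeledTable(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
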