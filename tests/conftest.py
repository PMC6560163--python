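import numpy as np
import pandas as pd
import pytest

from mycsig import DEFAULT_SIGNATURE, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_cohort(rng):
    """Random 21-gene x 24-sample matrix over all default signature + HK genes."""
    genes = list(DEFAULT_SIGNATURE.all_genes)
    samples = [f"P{i+1:02d}" for i in range(24)]
    values = rng.gamma(shape=4.0, scale=150.0, size=(len(genes), len(samples)))
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def make_matrix(values, genes=None, samples=None, meta=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), meta)
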