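import numpy as np
import pandas as pd
import pytest

from coregulon import DiscreteMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_expr(values, genes=None, samples=None, meta=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            sample_meta=meta)


def make_disc(states, genes=None, samples=None) -> DiscreteMatrix:
    states = np.asarray(states, dtype=int)
    genes = genes or [f"g{i}" for i in range(states.shape[0])]
    samples = samples or [f"s{j}" for j in range(states.shape[1])]
    return DiscreteMatrix(pd.DataFrame(states, index=genes, columns=samples))
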