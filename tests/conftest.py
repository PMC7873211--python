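import numpy as np
import pandas as pd
import pytest

from syndromics.containers import OutcomeMatrix


def make_outcome_matrix(X, metadata=None, prefix="v"):
    """Wrap a plain array as an OutcomeMatrix with opaque subject ids."""
    X = np.asarray(X, dtype=float)
    ids = [f"S{i:03d}" for i in range(X.shape[0])]
    df = pd.DataFrame(X, index=ids,
                      columns=[f"{prefix}{j}" for j in range(X.shape[1])])
    meta = (pd.DataFrame(index=df.index) if metadata is None
            else pd.DataFrame(metadata, index=df.index))
    return OutcomeMatrix(outcomes=df, metadata=meta)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_blob_outcomes():
    """60 subjects in two well-separated multivariate Gaussian blobs."""
    r = np.random.default_rng(5)
    X = np.vstack([r.normal(0, 0.5, (30, 4)), r.normal(8, 0.5, (30, 4))])
    return make_outcome_matrix(X)
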