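import warnings

import numpy as np
import pytest

from neuromark.cohort import DataMatrix
from neuromark.registry import canonical_columns, reduced_region_names

# classifier fits on tiny synthetic folds routinely hit iteration caps;
# convergence chatter is irrelevant to what the tests assert
warnings.filterwarnings("ignore", category=UserWarning)
try:
    from sklearn.exceptions import ConvergenceWarning

    warnings.filterwarnings("ignore", category=ConvergenceWarning)
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def reduced_columns():
    """The 64-column reduced universe (8 parcels x 4 morphologies x 2)."""
    return canonical_columns(reduced_region_names(4))


def make_matrix(X, y, columns=None, scope="global", sites=None):
    """Wrap plain arrays into a DataMatrix with dummy phenotypes."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    columns = columns if columns is not None else canonical_columns()[: X.shape[1]]
    return DataMatrix(
        scope=scope,
        columns=list(columns),
        values=X,
        labels=np.where(np.asarray(y) == 1, "ASD", "TD").astype(object),
        subject_ids=[f"s{i}" for i in range(n)],
        sites=list(sites) if sites is not None else ["-"] * n,
        ages=np.full(n, 12.0),
        sexes=["M"] * n,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
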