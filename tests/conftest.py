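import numpy as np
import pandas as pd
import pytest

from tristage.expression import ExpressionMatrix


def make_matrix(values, groups=("C", "C", "C", "M", "M", "M", "E", "E", "E"),
                genes=None, detected=None):
    """Build a small ExpressionMatrix from a 2-D array of log2 intensities."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    frame = pd.DataFrame(values, index=genes, columns=samples)
    group_series = pd.Series(list(groups[:n_samples]), index=samples)
    det = None
    if detected is not None:
        det = pd.DataFrame(np.atleast_2d(detected), index=genes, columns=samples).astype(bool)
    return ExpressionMatrix(frame, group_series, det)


@pytest.fixture
def rng():
    return np.random.default_rng(20280926)


@pytest.fixture
def three_group_matrix(rng):
    """100 null genes, 3 groups x 3 replicates, log2-ish intensities."""
    values = rng.normal(8.0, 1.0, size=(100, 9))
    return make_matrix(values)
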