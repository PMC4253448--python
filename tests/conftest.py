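import numpy as np
import pandas as pd
import pytest

from leukomir.preprocess import call_detection, normalize_and_log
from leukomir.simulate import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast unit tests; same structure as the default."""
    return SyntheticConfig(n_mirna=150, n_markers_per_celltype=5,
                           hidden_n_mirna=5, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale cohort (1205 miRNAs, 7v7 donors, 5 subsets + WB)."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def default_processed(default_cohort):
    m, sheet, truth = default_cohort
    det = call_detection(m, 0.0)
    log2m = normalize_and_log(m, sheet)
    return log2m, det, sheet, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_matrix(values, mirnas=None, samples=None, scale="log2"):
    from leukomir.types import ExpressionMatrix
    values = np.asarray(values, dtype=float)
    mirnas = mirnas or [f"m{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=mirnas, columns=samples), scale=scale)
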