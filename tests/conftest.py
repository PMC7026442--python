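import numpy as np
import pandas as pd
import pytest

from expolink import ExpressionStudy


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_study(values, study_id="S", n_case=None, genes=None):
    """Small helper: build a study whose first half of columns are cases."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_genes, n_samples = values.shape
    n_case = n_case if n_case is not None else n_samples // 2
    genes = genes or [f"GENE{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_samples)]
    group = pd.Series(["case"] * n_case + ["control"] * (n_samples - n_case),
                      index=samples)
    return ExpressionStudy(study_id, pd.DataFrame(values, index=genes, columns=samples),
                           group)


@pytest.fixture
def toy_study():
    return make_study(
        [[5.0, 5.2, 4.9, 1.0, 1.2, 0.8],
         [2.0, 2.1, 1.9, 2.0, 2.2, 1.8],
         [0.5, 0.3, 0.6, 3.5, 3.4, 3.6]],
    )
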