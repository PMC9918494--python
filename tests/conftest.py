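import numpy as np
import pandas as pd
import pytest

from immureg.io_formats import ExpressionMatrix
from immureg.synthetic_data import generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort (study conditions, fixed seed)."""
    return generate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast end-to-end plumbing tests."""
    return generate_cohort(
        n_tumor=40, n_normal=12, n_genes=60, n_tfs=12, n_clusters=4,
        n_atac=12, n_peaks=80, seed=3,
    )


@pytest.fixture()
def two_group_expr():
    """Tiny two-cluster + normal expression matrix for DE tests."""
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(6)]
    tumor = [f"t{i}" for i in range(8)]
    normal = [f"n{i}" for i in range(8)]
    values = pd.DataFrame(
        rng.uniform(10, 12, size=(6, 16)), index=genes, columns=tumor + normal
    )
    meta = pd.DataFrame(
        {
            "cohort": ["tumor"] * 8 + ["normal"] * 8,
            "cluster": [1] * 4 + [2] * 4 + [np.nan] * 8,
        },
        index=tumor + normal,
    )
    return ExpressionMatrix(values=values, sample_meta=meta)
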