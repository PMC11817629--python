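import numpy as np
import pandas as pd
import pytest

import hybridgo as hg


def make_matrix(values, row_prefix="g", col_prefix="s"):
    """Small OmicsMatrix from a nested list / array (NaN = missing)."""
    arr = np.asarray(values, dtype=float)
    return hg.OmicsMatrix(
        pd.DataFrame(
            arr,
            index=[f"{row_prefix}{i+1}" for i in range(arr.shape[0])],
            columns=[f"{col_prefix}{j+1}" for j in range(arr.shape[1])],
        )
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the package's standard study conditions."""
    return hg.generate_dataset(hg.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def prepared(default_dataset):
    """The default dataset filtered, imputed, and with features extracted."""
    return hg.prepare_synthetic(default_dataset)


@pytest.fixture(scope="session")
def small_cv(prepared):
    """A short hybrid RF cross-validation run shared across tests."""
    return hg.run_cv(prepared, n_bootstrap=3, seed=11)
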