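import numpy as np
import pytest

from utilmap import Dataset, default_paperlike_config, generate_cohort


@pytest.fixture(scope="session")
def paperlike_dataset() -> Dataset:
    """One study-conditions cohort (n = 446), shared across read-only tests."""
    return generate_cohort(default_paperlike_config(seed=1)).dataset()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20171101)


def random_scores_frame(rng: np.random.Generator, n: int):
    """Random valid subscale scores as a frame accepted by the predictors."""
    import pandas as pd

    return pd.DataFrame(
        {
            "pwb": rng.integers(0, 29, n),
            "swb": rng.integers(0, 29, n),
            "ewb": rng.integers(0, 25, n),
            "fwb": rng.integers(0, 29, n),
            "bcs": rng.integers(0, 41, n),
        }
    )
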