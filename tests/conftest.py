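import numpy as np
import pandas as pd
import pytest

from likertqca.config import reference_generator_config
from likertqca.synthetic import generate_survey


@pytest.fixture(scope="session")
def reference_survey():
    """A mid-sized draw from the reference survey design (no missingness)."""
    cfg = reference_generator_config(n_respondents=800, seed=20260919,
                                     missingness_rate=0.0)
    return generate_survey(cfg)


@pytest.fixture(scope="session")
def reference_survey_missing():
    """Same design with per-cell missingness switched on."""
    cfg = reference_generator_config(n_respondents=800, seed=20260920,
                                     missingness_rate=0.01)
    return generate_survey(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_items():
    """6 respondents x 3 items, the hand-checked reliability table."""
    return pd.DataFrame(
        [[1, 2, 3], [2, 2, 4], [3, 3, 5], [4, 3, 3], [5, 4, 4], [2, 1, 2]],
        columns=["I1", "I2", "I3"], dtype=float,
    )
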