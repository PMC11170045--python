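import numpy as np
import pytest

import trialcea as tc
from trialcea import pipeline


@pytest.fixture(scope="session")
def unit_table():
    return tc.default_unit_cost_table()


@pytest.fixture(scope="session")
def calibrated():
    return tc.calibrated_config(seed=2019)


@pytest.fixture(scope="session")
def small_complete():
    """Deterministic n=40 complete trial."""
    return tc.fixture_dataset(n_per_arm=(20, 20), seed=7)


@pytest.fixture(scope="session")
def small_with_dropout():
    return tc.fixture_dataset(n_per_arm=(20, 20), seed=7, with_dropout=True)


@pytest.fixture(scope="session")
def medium_with_dropout():
    """n=600 trial with MAR dropout, enough for imputation fits."""
    cfg = tc.calibrated_config(seed=31).replace(n_per_arm=(300, 300))
    ds = tc.apply_dropout(tc.generate_trial(cfg), cfg)
    return cfg, ds


@pytest.fixture(scope="session")
def medium_wide(medium_with_dropout, unit_table):
    _, ds = medium_with_dropout
    return pipeline.build_analysis_table(ds, unit_table)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
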