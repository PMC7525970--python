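import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from acescope import SyntheticConfig, simulate_dataset
from acescope.schema import COVARIATES, ITEMS, item_levels

settings.register_profile(
    "repeatable",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repeatable")


def make_row(
    items=None,
    covariates=None,
    outcome=0,
):
    """One respondent row with sensible defaults, overridable per column."""
    row = {item: item_levels(item)[0] for item in ITEMS}  # all unexposed
    if items:
        row.update(items)
    for cov, levels in COVARIATES.items():
        row[cov] = levels[0]
    if covariates:
        row.update(covariates)
    row["outcome"] = outcome
    return row


@pytest.fixture
def toy_screening_table():
    """10 rows: 6 complete, 2 with exactly one missing item, 1 with two
    missing items, 1 with a missing covariate."""
    rows = [make_row(outcome=i % 2) for i in range(6)]
    rows.append(make_row(items={"household_alcoholism": np.nan}))
    rows.append(make_row(items={"physical_abuse": np.nan}, outcome=1))
    rows.append(make_row(items={"divorce": np.nan, "forced_sex": np.nan}))
    rows.append(make_row(covariates={"income": np.nan}))
    return pd.DataFrame(rows)


@pytest.fixture
def worked_exposure_row():
    """The hand-counted row: items 1-5 = [yes,no,no,yes,no], items 6-11 =
    [never,once,more_than_once,never,once,never]. Score 5 under the 'once'
    threshold, 3 under 'more_than_once'."""
    binary = ["yes", "no", "no", "yes", "no"]
    freq = ["never", "once", "more_than_once", "never", "once", "never"]
    values = dict(zip(ITEMS, binary + freq))
    return pd.DataFrame([make_row(items=values)])


@pytest.fixture(scope="session")
def small_mir_dataset():
    """One synthetic dataset under the default MIR truth, reused across
    read-only tests."""
    return simulate_dataset(SyntheticConfig(n=2500, seed=42))
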