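import numpy as np
import pandas as pd
import pytest

import bfmsm as B


@pytest.fixture(scope="session")
def mid_config():
    """Moderate cohort with elevated mortality so matched/stratified
    analyses have events to work with."""
    return B.default_config(6000, seed=42, baseline_mortality_logit=-5.3)


@pytest.fixture(scope="session")
def mid_cohort(mid_config):
    return B.simulate_cohort(mid_config)


@pytest.fixture(scope="session")
def mid_person_months(mid_cohort):
    retained, _ = B.apply_exclusions(mid_cohort)
    return B.expand_person_months(retained)


@pytest.fixture(scope="session")
def big_person_months():
    """Default study conditions at n=20 000, expanded over the full age range."""
    cohort = B.simulate_cohort(B.default_config(20000, seed=7))
    retained, _ = B.apply_exclusions(cohort)
    return B.expand_person_months(retained)


COVARIATES = ("male", "education", "income_z")

PERSON_DEFAULTS = dict(
    entry_month=0, application_year=2011, entry_age_years=40.0,
    income_brl=100.0, municipality_id=0, deprivation_quintile=3,
    fhs_tercile=2, underreport_prob=0.0, excluded_ethnicity=False,
    treatment_start_month=None, death_month=None, death_cause=None,
    death_observed=True,
)


def make_persons(rows):
    """Build a small person table, filling unspecified fields with defaults."""
    full = []
    for i, row in enumerate(rows):
        r = dict(PERSON_DEFAULTS, person_id=i)
        r.update(row)
        full.append(r)
    df = pd.DataFrame(full, columns=["person_id"] + list(PERSON_DEFAULTS))
    for col in ("treatment_start_month", "death_month"):
        df[col] = df[col].astype("Int64")
    return df


def make_person_months(rows):
    """Small person-month table: rows of (person_id, t, treated, event[, initiation])."""
    df = pd.DataFrame(rows, columns=["person_id", "t", "treated", "event",
                                     "initiation"][: len(rows[0])])
    if "initiation" not in df:
        first_treated = df[df.treated == 1].groupby("person_id")["t"].min()
        df["initiation"] = [
            bool(tr == 1 and first_treated.get(p, -1) == t)
            for p, t, tr in zip(df.person_id, df.t, df.treated)]
    df["treated"] = df["treated"].astype(np.int8)
    df["event"] = df["event"].astype(np.int8)
    return df
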