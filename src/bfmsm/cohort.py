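"""Eligibility exclusions, income standardization and person-month expansion.

The analysis works in discrete months. Dates are floored to calendar
months indexed from the study start (month 0); ``admin_end`` is the
exclusive administrative end of follow-up. Risk periods are expanded to
one row per person-month, the canonical input for the discrete-time
(pooled logistic) hazard machinery downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import CVD_CAUSES, DEFAULT_THRESHOLD_TABLE

logger = logging.getLogger(__name__)

#: ordered exclusion rules; each person is counted under the first violated
EXCLUSION_RULES = (
    "died_before_registration",
    "age_over_100",
    "income_over_threshold",
    "excluded_ethnicity_flag",
    "applied_on_last_day_or_died_same_day",
    "same_month_award",  # optional robustness variant, off by default
)

#: entry-age bands used as a propensity-model covariate
AGE_BAND_EDGES = (0, 10, 20, 30, 40, 50, 60, 70, 200)
AGE_BAND_LABELS = ("0-9", "10-19", "20-29", "30-39", "40-49", "50-59", "60-69", "70+")


@dataclass
class ExclusionReport:
    """Per-rule exclusion counts; reconciles with the input size."""

    counts: dict
    retained: int
    total: int

    def __post_init__(self):
        if self.retained + sum(self.counts.values()) != self.total:
            raise ValueError("exclusion report does not reconcile")

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


def standardize_income(income, application_year, threshold_table: Mapping | None = None,
                       reference_year: int | None = None):
    """Rescale per-capita income to a reference year's eligibility threshold.

    Incomes recorded in different application years are made comparable by
    multiplying by ``threshold(reference_year) / threshold(application_year)``.
    Accepts scalars or aligned arrays; the reference year defaults to the
    latest year in the table.
    """
    table = dict(threshold_table or DEFAULT_THRESHOLD_TABLE)
    if reference_year is None:
        reference_year = max(table)
    if reference_year not in table:
        raise KeyError(f"reference year {reference_year} not in threshold table")
    for year, thr in table.items():
        if thr <= 0:
            raise ValueError(f"non-positive threshold for {year}")
    years = np.atleast_1d(np.asarray(application_year))
    missing = set(np.unique(years)) - set(table)
    if missing:
        raise KeyError(f"application year(s) {sorted(missing)} not in threshold table")
    factors = np.vectorize(lambda y: table[reference_year] / table[y])(years)
    out = np.atleast_1d(np.asarray(income, dtype=float)) * factors
    return float(out[0]) if np.isscalar(income) or np.ndim(income) == 0 else out


def apply_exclusions(persons: pd.DataFrame, income_cutoff: float = 300.0,
                     max_age: float = 100.0, admin_end: int = 60,
                     threshold_table: Mapping | None = None,
                     reference_year: int | None = None,
                     exclude_same_month_award: bool = False,
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the eligibility rules in order and report per-rule counts.

    Rules, in order: (i) death recorded before registration (linkage
    anomaly); (ii) older than ``max_age`` at registration; (iii)
    standardized per-capita income above ``income_cutoff``; (iv) flagged
    ethnicity group; (v) registered in the final follow-up month or died
    in the registration month. A person violating several rules counts
    once, under the first. ``exclude_same_month_award`` adds the
    robustness variant that drops persons whose benefit started in their
    registration month.
    """
    n = len(persons)
    if n == 0:
        report = ExclusionReport({r: 0 for r in EXCLUSION_RULES}, 0, 0)
        return persons.copy(), report

    death = persons["death_month"].to_numpy(dtype=float, na_value=np.nan)
    entry = persons["entry_month"].to_numpy()
    std_income = standardize_income(
        persons["income_brl"].to_numpy(dtype=float),
        persons["application_year"].to_numpy(),
        threshold_table, reference_year)
    treat = persons["treatment_start_month"].to_numpy(dtype=float, na_value=np.nan)

    masks = [
        death < entry,
        persons["entry_age_years"].to_numpy() > max_age,
        std_income > income_cutoff,
        persons["excluded_ethnicity"].to_numpy(dtype=bool),
        (entry >= admin_end) | (death == entry),
    ]
    if exclude_same_month_award:
        masks.append(treat == entry)
    else:
        masks.append(np.zeros(n, dtype=bool))

    rule_idx = np.full(n, -1)
    for i, m in enumerate(masks):
        rule_idx = np.where((rule_idx < 0) & m, i, rule_idx)
    counts = {r: int((rule_idx == i).sum()) for i, r in enumerate(EXCLUSION_RULES)}
    keep = rule_idx < 0
    report = ExclusionReport(counts, int(keep.sum()), n)
    retained = persons.loc[keep].copy()
    retained["income_standardized"] = std_income[keep]
    return retained, report


def assign_age_band(age_years) -> pd.Categorical:
    """Entry-age band labels (10-year bands, 70+ pooled)."""
    return pd.cut(np.asarray(age_years, dtype=float), bins=AGE_BAND_EDGES,
                  labels=AGE_BAND_LABELS, right=False)


def expand_person_months(persons: pd.DataFrame,
                         age_window: tuple[float, float] | None = None,
                         admin_end: int = 60,
                         cause: str = "all") -> pd.DataFrame:
    """Expand persons into one row per month at risk.

    The risk period starts at registration or on reaching the lower age
    bound, whichever is later, and ends at the earliest of observed
    death, the administrative end, or the month before reaching the upper
    age bound (ages half-open ``[low, high)``). Persons whose benefit
    started before their risk period count as treated from ``t = 0``.
    ``event`` is 1 on the final row iff the death was registered, falls
    inside the window and matches ``cause`` ('all', 'cvd', or a specific
    cause class). Unregistered deaths look censored at the administrative
    end — deliberately, since that is the bias the under-reporting
    restriction probes.
    """
    if age_window is not None and age_window[0] >= age_window[1]:
        raise ValueError("inverted age window")
    low, high = age_window if age_window is not None else (None, None)

    entry = persons["entry_month"].to_numpy(dtype=np.int64)
    age = persons["entry_age_years"].to_numpy(dtype=float)
    death = persons["death_month"].to_numpy(dtype=float, na_value=np.nan)
    observed = persons["death_observed"].to_numpy(dtype=bool)
    obs_death = np.where(np.isnan(death) | ~observed, np.inf, death)

    start = entry.astype(float)
    if low is not None:
        start = np.maximum(start, entry + np.ceil(np.maximum(0.0, (low - age)) * 12))
    end = np.minimum(obs_death, admin_end - 1)
    if high is not None:
        # last month with attained age strictly below `high`
        end = np.minimum(end, entry + np.ceil((high - age) * 12) - 1)
    dur = (end - start + 1).clip(min=0)
    keep = dur > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("expand_person_months: %d person(s) contribute zero months",
                    n_dropped)

    p = persons.loc[keep].reset_index(drop=True)
    start, end, dur = start[keep], end[keep], dur[keep].astype(np.int64)
    obs_death = obs_death[keep]
    ridx = np.repeat(np.arange(len(p)), dur)
    t = np.arange(dur.sum()) - np.repeat(np.cumsum(dur) - dur, dur)
    cal = start[ridx].astype(np.int64) + t

    treat = p["treatment_start_month"].to_numpy(dtype=float, na_value=np.inf)
    treated = (cal >= treat[ridx]).astype(np.int8)
    initiation = (cal == treat[ridx]) & (treated == 1)

    is_last = t == (dur[ridx] - 1)
    died_here = is_last & (cal == obs_death[ridx])
    if cause != "all":
        cause_ok = (p["death_cause"].isin(CVD_CAUSES) if cause == "cvd"
                    else p["death_cause"] == cause).to_numpy()
        died_here &= cause_ok[ridx]
    event = died_here.astype(np.int8)

    out = pd.DataFrame({
        "person_id": p["person_id"].to_numpy()[ridx],
        "t": t.astype(np.int64),
        "calendar_month": cal,
        "age_years": p["entry_age_years"].to_numpy()[ridx]
        + (cal - p["entry_month"].to_numpy()[ridx]) / 12.0,
        "treated": treated,
        "event": event,
        "initiation": initiation,
    })
    out["age_band"] = assign_age_band(p["entry_age_years"].to_numpy()[ridx])
    carry = [c for c in p.columns if c not in
             {"person_id", "entry_month", "treatment_start_month", "death_month",
              "death_cause", "death_observed", "entry_age_years"}]
    for c in carry:
        out[c] = p[c].to_numpy()[ridx]
    return out
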