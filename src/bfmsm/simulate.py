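"""Synthetic open-cohort generator with known ground truth.

Each person enters the registry at a staggered calendar month, then in
every month at risk may (while untreated) start the benefit with
probability ``expit(uptake logit)`` and may die with probability
``expit(mortality logit)``, where the mortality logit includes the true
treatment effect for months under benefit. Treatment is absorbing.
Deaths go unregistered with their municipality's under-reporting
probability, in which case the record looks administratively censored.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CAUSE_LEVELS, SimulationConfig

PERSON_COLUMNS = [
    "person_id", "entry_month", "application_year", "entry_age_years",
    "income_brl", "municipality_id", "deprivation_quintile", "fhs_tercile",
    "underreport_prob", "excluded_ethnicity", "treatment_start_month",
    "death_month", "death_cause", "death_observed",
]


def _draw_confounders(rng: np.random.Generator, config: SimulationConfig, n: int):
    """Draw covariate columns and their additive logit contributions."""
    cols: dict[str, np.ndarray] = {}
    uptake_lp = np.zeros(n)
    mort_lp = np.zeros(n)
    for c in config.confounder_spec:
        if c.kind == "binary":
            x = (rng.random(n) < c.dist[0]).astype(np.int8)
            cols[c.name] = x
            uptake_lp += float(c.uptake_beta) * x
            mort_lp += float(c.mortality_beta) * x
        elif c.kind == "categorical":
            levels, probs = c.dist
            idx = rng.choice(len(levels), size=n, p=np.asarray(probs, float))
            cols[c.name] = pd.Categorical.from_codes(idx, categories=list(levels))
            ub = np.broadcast_to(np.atleast_1d(c.uptake_beta), (len(levels),))
            mb = np.broadcast_to(np.atleast_1d(c.mortality_beta), (len(levels),))
            uptake_lp += np.asarray(ub, float)[idx]
            mort_lp += np.asarray(mb, float)[idx]
        else:
            mean, sd = c.dist
            x = rng.normal(mean, sd, size=n)
            cols[c.name] = x
            uptake_lp += float(c.uptake_beta) * x
            mort_lp += float(c.mortality_beta) * x
    return cols, uptake_lp, mort_lp


def _draw_municipalities(rng: np.random.Generator, config: SimulationConfig, n: int):
    """Assign municipalities and their fixed attributes.

    Deprivation quintiles are rank-based over municipality ids; FHS
    coverage terciles come from an independent permutation so the two
    stratifiers are not collinear.
    """
    n_mun = config.n_municipalities
    quintile_of_mun = 1 + (5 * np.arange(n_mun)) // n_mun
    perm = rng.permutation(n_mun)
    tercile_of_mun = 1 + (3 * perm) // n_mun
    under_of_mun = config.resolve_underreporting()
    mun = rng.integers(0, n_mun, size=n)
    return mun, quintile_of_mun[mun], tercile_of_mun[mun], under_of_mun[mun]


def _entry_ages(rng, config, n):
    kind, lo, hi = config.entry_age_distribution
    if kind != "uniform":
        raise ValueError(f"unsupported entry age distribution {kind!r}")
    return rng.uniform(lo, hi, size=n)


def _time_trend(config: SimulationConfig, t: int) -> float:
    return sum(c * t ** (k + 1) for k, c in enumerate(config.uptake_time_trend))


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate one synthetic cohort as a person-level table.

    Returns one row per person with baseline covariates, municipality
    attributes and (possibly missing) treatment-start and death months.
    Identical configs (including seed) give identical output.
    """
    config.validate()
    n = config.n_persons
    rng = np.random.default_rng(config.seed)

    cols, uptake_lp, mort_lp = _draw_confounders(rng, config, n)
    mun, quintile, tercile, under = _draw_municipalities(rng, config, n)
    entry_age = _entry_ages(rng, config, n)
    if config.staggered_entry:
        entry = rng.integers(0, config.admin_end, size=n)
    else:
        entry = np.zeros(n, dtype=np.int64)
    kind, lo, hi = config.income_distribution
    income = rng.uniform(lo, hi, size=n)
    ethnicity_flag = rng.random(n) < config.excluded_ethnicity_prob

    uptake_lp = uptake_lp + config.baseline_uptake_logit \
        + config.deprivation_effect_on_uptake * (quintile - 3)
    mort_lp = mort_lp + config.baseline_mortality_logit \
        + config.deprivation_effect_on_mortality * (quintile - 3)
    if not (np.all(np.isfinite(mort_lp)) and np.all(np.isfinite(uptake_lp))):
        raise ValueError("non-finite linear predictor; check covariate effects")

    if config.true_log_hr_by_quintile is not None:
        log_hr = np.asarray(config.true_log_hr_by_quintile, float)[quintile - 1]
    else:
        log_hr = np.full(n, config.true_log_hr)

    treat_start = np.full(n, -1, dtype=np.int64)
    death_month = np.full(n, -1, dtype=np.int64)
    alive = np.ones(n, dtype=bool)
    max_t = np.minimum(config.horizon_months, config.admin_end - entry)

    for t in range(config.horizon_months):
        at_risk = alive & (t < max_t)
        if not at_risk.any():
            break
        untreated = at_risk & (treat_start < 0)
        if untreated.any():
            p_up = expit(uptake_lp[untreated] + _time_trend(config, t))
            starts = rng.random(untreated.sum()) < p_up
            idx = np.flatnonzero(untreated)[starts]
            treat_start[idx] = entry[idx] + t
        treated_now = at_risk & (treat_start >= 0)
        p_death = expit(mort_lp[at_risk] + log_hr[at_risk] * treated_now[at_risk])
        dies = rng.random(at_risk.sum()) < p_death
        idx = np.flatnonzero(at_risk)[dies]
        death_month[idx] = entry[idx] + t
        alive[idx] = False

    dead = death_month >= 0
    observed = np.ones(n, dtype=bool)
    observed[dead] = rng.random(dead.sum()) >= under[dead]
    causes, cause_p = zip(*config.cause_probs)
    cause_idx = rng.choice(len(causes), size=n, p=np.asarray(cause_p))
    death_cause = pd.array(
        np.where(dead, np.asarray(causes, object)[cause_idx], None), dtype="object"
    )

    df = pd.DataFrame({
        "person_id": np.arange(n, dtype=np.int64),
        "entry_month": entry,
        "application_year": np.minimum(config.start_year + entry // 12,
                                       config.start_year + (config.admin_end - 1) // 12),
        "entry_age_years": entry_age,
        **cols,
        "income_brl": income,
        "municipality_id": mun,
        "deprivation_quintile": quintile.astype(np.int8),
        "fhs_tercile": tercile.astype(np.int8),
        "underreport_prob": under,
        "excluded_ethnicity": ethnicity_flag,
        "treatment_start_month": pd.array(
            np.where(treat_start >= 0, treat_start, pd.NA), dtype="Int64"),
        "death_month": pd.array(
            np.where(dead, death_month, pd.NA), dtype="Int64"),
        "death_cause": death_cause,
        "death_observed": observed,
    })
    return df


def counterfactual_marginal_hr(config: SimulationConfig, n_oracle: int,
                               seed: int | None = None) -> float:
    """Ground-truth marginal hazard ratio by counterfactual simulation.

    Simulates two arms on the same ``n_oracle`` baseline draws — everyone
    treated from entry versus never treated — with common monthly random
    numbers, then computes the pooled person-month odds ratio of death,
    i.e. the exact maximum-likelihood fit of a discrete-time hazard model
    of event on treatment alone. This is the recovery target for the
    weighted analysis: it marginalizes the conditional effect over the
    covariate distribution (hazard ratios are non-collapsible, so it need
    not equal ``exp(true_log_hr)``).
    """
    if n_oracle < 1:
        raise ValueError("n_oracle must be positive")
    rng = np.random.default_rng(
        (config.seed + 987_654_321) % 2**31 if seed is None else seed)
    n = n_oracle
    _, _, mort_lp = _draw_confounders(rng, config, n)
    _, quintile, _, _ = _draw_municipalities(rng, config, n)
    if config.staggered_entry:
        entry = rng.integers(0, config.admin_end, size=n)
    else:
        entry = np.zeros(n, dtype=np.int64)
    mort_lp = mort_lp + config.baseline_mortality_logit \
        + config.deprivation_effect_on_mortality * (quintile - 3)
    max_t = np.minimum(config.horizon_months, config.admin_end - entry)

    if config.true_log_hr_by_quintile is not None:
        log_hr = np.asarray(config.true_log_hr_by_quintile, float)[quintile - 1]
    else:
        log_hr = np.full(n, config.true_log_hr)
    p1 = expit(mort_lp + log_hr)
    p0 = expit(mort_lp)
    alive1 = np.ones(n, dtype=bool)
    alive0 = np.ones(n, dtype=bool)
    events = np.zeros(2, dtype=np.int64)
    pmonths = np.zeros(2, dtype=np.int64)
    for t in range(config.horizon_months):
        in_fu = t < max_t
        r1 = alive1 & in_fu
        r0 = alive0 & in_fu
        if not (r1.any() or r0.any()):
            break
        u = rng.random(n)
        d1 = r1 & (u < p1)
        d0 = r0 & (u < p0)
        events += (d1.sum(), d0.sum())
        pmonths += (r1.sum(), r0.sum())
        alive1[d1] = False
        alive0[d0] = False

    if events[0] == 0 or events[1] == 0:
        raise ValueError("zero events in a counterfactual arm; increase n_oracle")
    odds1 = events[0] / (pmonths[0] - events[0])
    odds0 = events[1] / (pmonths[1] - events[1])
    return float(odds1 / odds0)


# -- flat-file round trip ----------------------------------------------------

def write_cohort(df: pd.DataFrame, path: str | Path,
                 config: SimulationConfig | None = None) -> None:
    """Write the person table as CSV plus a JSON sidecar echoing the config."""
    path = Path(path)
    df.to_csv(path, index=False)
    if config is not None:
        sidecar = path.with_suffix(path.suffix + ".config.json")
        sidecar.write_text(config.to_json(indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("treatment_start_month", "death_month"):
        if col in df:
            df[col] = df[col].astype("Int64")
    return df
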