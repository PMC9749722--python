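"""Marginal structural model: cumulative IPT weights and the weighted
discrete-time hazard fit.

The monthly contribution to the denominator of the weight is the
probability of the person's observed treatment state that month: PS in
the initiation month, 1−PS while untreated, and 1 once treated (the
exposure is absorbing). The cumulative product over months is the
probability of the observed treatment history; its inverse is the IPT
weight. Stabilized weights (default) multiply by the analogous cumulative
probability from a covariate-free, time-only initiation model, which
keeps the weighted pseudo-population the same size as the cohort.

The outcome model is a pooled logistic regression of the monthly event
indicator on treatment and a natural cubic spline of follow-up time
(the discrete-time baseline hazard), with the weight as a variance
weight and a cluster-robust sandwich variance clustered on persons.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import SpecificationWarning

from .propensity import (DEFAULT_PERCENTILES, PSModel, SplineSpec, build_design,
                         fit_ps_model, predict_ps, resolve_knots)

logger = logging.getLogger(__name__)

Z95 = float(stats.norm.ppf(0.975))


@dataclass
class WeightSeries:
    """Per person-month weight components plus summary diagnostics."""

    frame: pd.DataFrame  # person_id, t, contribution, cumulative, weight
    diagnostics: dict

    @property
    def weights(self) -> np.ndarray:
        return self.frame["weight"].to_numpy()


@dataclass
class MSMResult:
    """Treatment effect from one weighted (or unweighted) hazard fit."""

    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    n_persons: int
    n_person_months: int
    n_events: int
    stratum: str = "overall"

    def __post_init__(self):
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the HR")

    def to_dict(self) -> dict:
        return asdict(self)


def _check_sorted(pm: pd.DataFrame) -> pd.DataFrame:
    order = np.lexsort((pm["t"].to_numpy(), pm["person_id"].to_numpy()))
    if not np.array_equal(order, np.arange(len(pm))):
        pm = pm.iloc[order]
    return pm


def compute_weights(person_months: pd.DataFrame, ps: np.ndarray,
                    stabilize: bool = True,
                    truncate_percentiles: tuple | None = None,
                    numerator_ps: np.ndarray | None = None,
                    literal: bool = False,
                    max_weight_flag: float = 10.0) -> WeightSeries:
    """Build cumulative inverse-probability-of-treatment weights.

    ``ps`` is the monthly initiation probability per row (1 after
    initiation), aligned with ``person_months``. With ``stabilize`` the
    numerator probabilities come from ``numerator_ps`` or, if absent,
    from a time-only initiation model fitted here. ``literal`` returns
    the cumulative observed-history probability itself as the weight
    (the non-inverted reading of the weighting text) for comparison.
    ``truncate_percentiles`` clamps the final weights at the stated
    percentiles, e.g. ``(1, 99)``.
    """
    ps = np.asarray(ps, dtype=float)
    if len(ps) != len(person_months):
        raise ValueError("ps must align with person_months rows")
    order = np.lexsort((person_months["t"].to_numpy(),
                        person_months["person_id"].to_numpy()))
    if np.array_equal(order, np.arange(len(person_months))):
        pm = person_months
    else:
        pm = person_months.iloc[order]
        ps = ps[order]
    treated = pm["treated"].to_numpy()
    post = (treated == 1) & ~pm["initiation"].to_numpy()
    if np.any(ps[post] != 1.0):
        raise ValueError("post-initiation propensity must be exactly 1")
    pre = ~post
    if np.any((ps[pre] <= 0) | (ps[pre] >= 1)):
        raise ValueError("pre-initiation propensity must lie strictly in (0,1)")

    contribution = np.where(treated == 1, ps, 1.0 - ps)
    cumulative = pd.Series(contribution).groupby(
        pm["person_id"].to_numpy()).cumprod().to_numpy()
    if np.any(cumulative <= 0):
        raise ValueError("zero cumulative treatment-history probability")

    if literal:
        weight = cumulative.copy()
    elif stabilize:
        if numerator_ps is None:
            num_model = fit_ps_model(pm, covariates=())
            numerator_ps = predict_ps(num_model, pm)
        numerator_ps = np.asarray(numerator_ps, dtype=float)
        num_contrib = np.where(treated == 1, numerator_ps, 1.0 - numerator_ps)
        num_cum = pd.Series(num_contrib).groupby(
            pm["person_id"].to_numpy()).cumprod().to_numpy()
        weight = num_cum / cumulative
    else:
        weight = 1.0 / cumulative

    if truncate_percentiles is not None:
        lo, hi = np.percentile(weight, truncate_percentiles)
        weight = np.clip(weight, lo, hi)

    diagnostics = {
        "mean": float(weight.mean()),
        "max": float(weight.max()),
        "p1": float(np.percentile(weight, 1)),
        "p99": float(np.percentile(weight, 99)),
        "stabilized": bool(stabilize and not literal),
        "truncated_at": truncate_percentiles,
        "flag_max_weight": bool(weight.max() > max_weight_flag),
    }
    if diagnostics["flag_max_weight"]:
        logger.warning("maximum weight %.2f exceeds %.1f; check overlap",
                       diagnostics["max"], max_weight_flag)
    frame = pd.DataFrame({
        "person_id": pm["person_id"].to_numpy(), "t": pm["t"].to_numpy(),
        "contribution": contribution, "cumulative": cumulative, "weight": weight,
    }, index=pm.index)
    return WeightSeries(frame, diagnostics)


def fit_msm(person_months: pd.DataFrame, weights: np.ndarray | None = None,
            spline: SplineSpec | None = None, cov_type: str = "cluster",
            stratum: str = "overall") -> MSMResult:
    """Weighted pooled logistic regression of event on treatment + spline(t).

    The sandwich variance is clustered on persons by default
    (``cov_type='cluster'``); ``'nonrobust'`` gives the model-based SE.
    """
    pm = _check_sorted(person_months)
    y = pm["event"].to_numpy(dtype=float)
    events_by_arm = pd.Series(y).groupby(pm["treated"].to_numpy()).sum()
    if len(events_by_arm) < 2 or (events_by_arm < 1).any():
        raise ValueError("need at least one event in each treatment state")
    if spline is None:
        spline = resolve_knots(pm["t"].to_numpy(), DEFAULT_PERCENTILES)
    X, _ = build_design(pm, ("treated",), spline)
    w = np.ones(len(pm)) if weights is None else np.asarray(weights, dtype=float)
    glm = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
    with warnings.catch_warnings():
        # the var_weights sandwich here equals the GEE independence robust
        # variance (verified against sm.GEE); statsmodels' blanket warning
        # about var_weights + cov_type does not apply to this use
        warnings.filterwarnings("ignore", category=SpecificationWarning)
        if cov_type == "cluster":
            res = glm.fit(cov_type="cluster",
                          cov_kwds={"groups": pm["person_id"].to_numpy()})
        else:
            res = glm.fit(cov_type=cov_type)
    if not res.converged:
        raise RuntimeError("outcome model did not converge")
    beta = float(res.params["treated"])
    se = float(res.bse["treated"])
    return MSMResult(
        beta=beta, se=se, hr=math.exp(beta),
        ci_low=math.exp(beta - Z95 * se), ci_high=math.exp(beta + Z95 * se),
        n_persons=int(pm["person_id"].nunique()), n_person_months=len(pm),
        n_events=int(y.sum()), stratum=stratum)


def iptw_msm(person_months: pd.DataFrame, covariates=(),
             stabilize: bool = True, truncate_percentiles: tuple | None = None,
             literal: bool = False, cov_type: str = "cluster",
             stratum: str = "overall"):
    """Full pipeline on expanded person-months: fit the initiation model,
    build cumulative weights, fit the weighted hazard model.

    Returns ``(MSMResult, WeightSeries, PSModel)``.
    """
    ps_model = fit_ps_model(person_months, covariates=covariates)
    ps = predict_ps(ps_model, person_months)
    ws = compute_weights(person_months, ps, stabilize=stabilize,
                         truncate_percentiles=truncate_percentiles,
                         literal=literal)
    result = fit_msm(person_months, ws.weights, cov_type=cov_type,
                     stratum=stratum)
    return result, ws, ps_model


STRATUM_VARIABLES = ("deprivation_quintile", "fhs_tercile", "age_band")
#: covariates removed from the PS when stratifying on a deprivation proxy
REGION_PROXIES = ("deprivation_quintile", "region")


def stratified_msm(person_months: pd.DataFrame, stratum_variable: str,
                   covariates=(), stabilize: bool = True,
                   truncate_percentiles: tuple | None = None,
                   min_events: int = 2, cov_type: str = "cluster"):
    """Independent weight construction and MSM fit within each stratum.

    The initiation model is refitted per stratum; when stratifying by
    deprivation quintile, region-like covariates are removed from the PS.
    Strata with fewer than ``min_events`` events are skipped with a
    logged reason. Returns a list of MSMResult ordered by stratum.
    """
    if stratum_variable not in STRATUM_VARIABLES:
        raise ValueError(f"unknown stratum variable {stratum_variable!r}; "
                         f"choose from {STRATUM_VARIABLES}")
    covs = tuple(covariates)
    if stratum_variable == "deprivation_quintile":
        covs = tuple(c for c in covs if c not in REGION_PROXIES)
    covs = tuple(c for c in covs if c != stratum_variable)
    results = []
    col = person_months[stratum_variable]
    levels = [l for l in (col.cat.categories if isinstance(col.dtype, pd.CategoricalDtype)
                          else sorted(col.dropna().unique()))
              if (col == l).any()]
    for level in levels:
        sub = person_months.loc[col == level]
        n_events = int(sub["event"].sum())
        if n_events < min_events:
            logger.info("stratum %s=%s skipped: %d event(s)",
                        stratum_variable, level, n_events)
            continue
        res, _, _ = iptw_msm(sub, covs, stabilize=stabilize,
                             truncate_percentiles=truncate_percentiles,
                             cov_type=cov_type,
                             stratum=f"{stratum_variable}={level}")
        results.append(res)
    return results


def results_table(results) -> pd.DataFrame:
    """Tabulate MSMResults (stratum, HR, CI, counts) for export."""
    return pd.DataFrame([r.to_dict() for r in results])
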