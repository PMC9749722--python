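"""Sensitivity and robustness procedures around the main weighted analysis.

* E-values (VanderWeele–Ding): the minimum strength of association, on
  the risk-ratio scale, that an unmeasured confounder would need with
  both treatment and outcome to explain away an observed hazard ratio.
* Risk-set matching: each benefit initiator is matched, at its
  initiation month, to a not-yet-treated person with the nearest
  propensity score, followed by a conditional (matched-set) hazard fit.
* Covariate-adjusted discrete-time hazard fit, plus a true partial-
  likelihood Cox fit with the benefit as a time-varying covariate, used
  to check the rare-event equivalence of the two formulations.
* Restriction to municipalities with near-complete death registration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxTimeVaryingFitter
from statsmodels.discrete.conditional_models import ConditionalLogit

from .msm import MSMResult, Z95, _check_sorted, fit_msm
from .propensity import build_design, resolve_knots

logger = logging.getLogger(__name__)


# -- e-values -----------------------------------------------------------------

@dataclass
class EValueResult:
    point: float
    ci_limit: float | None = None


def _evalue_transform(rr: float) -> float:
    rr_star = rr if rr >= 1.0 else 1.0 / rr
    return rr_star + math.sqrt(rr_star * (rr_star - 1.0))


def evalue(hr: float, ci: tuple[float, float] | None = None) -> EValueResult:
    """VanderWeele–Ding e-value for a hazard ratio (rare outcome).

    Protective estimates are inverted before the transformation
    ``E = RR* + sqrt(RR*(RR*-1))``. The CI e-value uses the confidence
    limit closer to the null and equals 1 when the interval crosses 1.
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be positive")
    point = _evalue_transform(hr)
    ci_limit = None
    if ci is not None:
        lo, hi = ci
        if lo <= 0 or hi < lo:
            raise ValueError("invalid confidence interval")
        if lo <= 1.0 <= hi:
            ci_limit = 1.0
        else:
            ci_limit = _evalue_transform(hi if hi < 1.0 else lo)
    return EValueResult(point, ci_limit)


# -- risk-set matching --------------------------------------------------------

def risk_set_match(person_months: pd.DataFrame, ps: np.ndarray,
                   caliper: float | None = None):
    """1:1 greedy nearest-neighbour risk-set matching without replacement.

    Initiation months are visited in order; each initiator is matched to
    the unused person with the nearest propensity score among those still
    untreated at that month (future initiators may serve as controls and
    are censored at their own initiation in the matched analysis). The
    default caliper is 0.2 × SD of logit(PS) over pre-initiation rows.
    Returns ``(pairs, diagnostics)``; pairs has one row per matched set.
    """
    pm = person_months
    ps = np.asarray(ps, dtype=float)
    pre = (pm["treated"].to_numpy() == 0) | pm["initiation"].to_numpy()
    if caliper is None:
        lps = np.log(ps[pre] / (1 - ps[pre]))
        caliper = 0.2 * float(np.std(lps))
    if caliper <= 0:
        raise ValueError("caliper must be positive")

    pid = pm["person_id"].to_numpy()
    t = pm["t"].to_numpy()
    init_rows = pm["initiation"].to_numpy()
    untreated = pm["treated"].to_numpy() == 0
    init_t = pd.Series(t[init_rows], index=pid[init_rows])  # initiators only

    pairs, unmatched = [], []
    used: set[int] = set()
    for month in sorted(init_t.unique()):
        rows_m = t == month
        # candidates are untreated at `month` (hence at risk and their own
        # initiation, if any, lies in the future)
        cand_mask = rows_m & untreated
        cand_ids = pid[cand_mask]
        cand_order = np.argsort(cand_ids)
        cand_ids = cand_ids[cand_order]
        cand_ps = ps[cand_mask][cand_order]
        alive = np.array([c not in used for c in cand_ids], dtype=bool)
        ps_init = pd.Series(ps[rows_m & init_rows], index=pid[rows_m & init_rows])
        for i in sorted(ps_init.index):
            if not alive.any():
                unmatched.append((int(i), int(month), "no control available"))
                continue
            d = np.abs(cand_ps - ps_init[i])
            d[~alive] = np.inf
            j = int(np.argmin(d))  # ties: argmin takes lowest index = lowest id
            if d[j] > caliper:
                unmatched.append((int(i), int(month), "no control within caliper"))
                continue
            pairs.append({"set_id": len(pairs), "month": int(month),
                          "initiator": int(i), "control": int(cand_ids[j]),
                          "initiator_ps": float(ps_init[i]),
                          "control_ps": float(cand_ps[j]),
                          "distance": float(d[j])})
            alive[j] = False
            used.add(int(cand_ids[j]))
            used.add(int(i))
    pairs_df = pd.DataFrame(pairs, columns=["set_id", "month", "initiator",
                                            "control", "initiator_ps",
                                            "control_ps", "distance"])
    diagnostics = {
        "n_initiators": int(len(init_t)),
        "n_matched": len(pairs_df),
        "match_rate": len(pairs_df) / len(init_t) if len(init_t) else float("nan"),
        "caliper": float(caliper),
        "unmatched": unmatched,
    }
    return pairs_df, diagnostics


def matched_hazard_fit(pairs: pd.DataFrame,
                       person_months: pd.DataFrame) -> MSMResult:
    """Conditional (matched-set stratified) discrete-time hazard fit.

    From each matched month onward the initiator contributes treated
    months and the control untreated months, the control censored at its
    own later initiation. A conditional logistic regression of the event
    on treatment, stratified on matched set, returns the HR.
    """
    if len(pairs) == 0:
        raise ValueError("no matched sets")
    pm = _check_sorted(person_months)
    pid = pm["person_id"].to_numpy()
    t = pm["t"].to_numpy()
    event = pm["event"].to_numpy()
    init_first = pm.loc[pm["initiation"].to_numpy()].set_index("person_id")["t"]
    # person-major sorted rows: locate each person's block once
    uniq, starts = np.unique(pid, return_index=True)
    ends = np.r_[starts[1:], len(pid)]
    rows = dict(zip(uniq, zip(starts, ends)))
    blocks = []
    for row in pairs.itertuples():
        m = row.month
        lo, hi = rows[row.initiator]
        sel = slice(lo + np.searchsorted(t[lo:hi], m), hi)
        blocks.append((t[sel], event[sel], 1, row.set_id))
        lo, hi = rows[row.control]
        ctl_end = init_first.get(row.control, np.inf)
        lo2 = lo + np.searchsorted(t[lo:hi], m)
        hi2 = lo + np.searchsorted(t[lo:hi], ctl_end)
        blocks.append((t[lo2:hi2], event[lo2:hi2], 0, row.set_id))
    data = pd.DataFrame({
        "t": np.concatenate([b[0] for b in blocks]),
        "event": np.concatenate([b[1] for b in blocks]),
        "treated": np.concatenate([np.full(len(b[0]), b[2], dtype=np.int8)
                                   for b in blocks]),
        "set_id": np.concatenate([np.full(len(b[0]), b[3], dtype=np.int64)
                                  for b in blocks]),
    })
    has_event = data.groupby("set_id")["event"].transform("max") > 0
    data = data.loc[has_event]
    if len(data) == 0:
        raise ValueError("no matched set contains an event")
    res = ConditionalLogit(data["event"].to_numpy(dtype=float),
                           data[["treated"]].to_numpy(dtype=float),
                           groups=data["set_id"].to_numpy()).fit(disp=0)
    beta, se = float(res.params[0]), float(res.bse[0])
    return MSMResult(beta=beta, se=se, hr=math.exp(beta),
                     ci_low=math.exp(beta - Z95 * se),
                     ci_high=math.exp(beta + Z95 * se),
                     n_persons=int(pd.concat([pairs["initiator"],
                                              pairs["control"]]).nunique()),
                     n_person_months=len(data),
                     n_events=int(data["event"].sum()),
                     stratum="risk-set matched")


# -- covariate-adjusted fits --------------------------------------------------

def adjusted_hazard_fit(person_months: pd.DataFrame, covariates=(),
                        cov_type: str = "cluster") -> MSMResult:
    """Unweighted discrete-time hazard model adjusted for covariates.

    Pooled logistic regression of event on treatment, baseline covariates
    and a spline of follow-up time — the discrete-time analogue of a
    covariate-adjusted Cox model with a time-varying exposure.
    """
    pm = _check_sorted(person_months)
    y = pm["event"].to_numpy(dtype=float)
    if y.sum() < 1:
        raise ValueError("no events")
    spline = resolve_knots(pm["t"].to_numpy())
    X, _ = build_design(pm, ("treated",) + tuple(covariates), spline)
    glm = sm.GLM(y, X, family=sm.families.Binomial())
    if cov_type == "cluster":
        res = glm.fit(cov_type="cluster",
                      cov_kwds={"groups": pm["person_id"].to_numpy()})
    else:
        res = glm.fit(cov_type=cov_type)
    if not res.converged:
        raise RuntimeError("adjusted hazard model did not converge")
    beta, se = float(res.params["treated"]), float(res.bse["treated"])
    return MSMResult(beta=beta, se=se, hr=math.exp(beta),
                     ci_low=math.exp(beta - Z95 * se),
                     ci_high=math.exp(beta + Z95 * se),
                     n_persons=int(pm["person_id"].nunique()),
                     n_person_months=len(pm), n_events=int(y.sum()),
                     stratum="covariate adjusted")


def to_counting_process(person_months: pd.DataFrame,
                        covariates=()) -> pd.DataFrame:
    """Collapse person-months into start/stop intervals of constant
    treatment for partial-likelihood fitting (at most two per person)."""
    pm = _check_sorted(person_months)
    g = pm.groupby(["person_id", "treated"], sort=True, observed=True)
    agg = g.agg(start=("t", "min"), last=("t", "max"), event=("event", "max"),
                **{c: (c, "first") for c in covariates}).reset_index()
    agg["stop"] = agg["last"] + 1
    return agg.drop(columns="last")


def cox_time_varying_fit(person_months: pd.DataFrame, covariates=()):
    """Cox partial-likelihood fit with the benefit as a time-varying
    covariate (Breslow tie handling, via lifelines). Used as the
    continuous-time cross-check of the pooled logistic HR."""
    cp = to_counting_process(person_months, covariates)
    num_covs = []
    for c in covariates:
        col = cp[c]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True,
                                     dtype=float)
            cp = pd.concat([cp.drop(columns=c), dummies], axis=1)
            num_covs += list(dummies.columns)
        else:
            num_covs.append(c)
    ctv = CoxTimeVaryingFitter()
    ctv.fit(cp[["person_id", "start", "stop", "event", "treated"] + num_covs],
            id_col="person_id", event_col="event",
            start_col="start", stop_col="stop")
    return ctv


# -- under-reporting restriction ----------------------------------------------

def restrict_to_low_underreporting(persons: pd.DataFrame,
                                   threshold: float = 0.005) -> pd.DataFrame:
    """Keep persons in municipalities with death under-reporting
    probability below ``threshold`` (default 0.5%)."""
    if "underreport_prob" not in persons.columns:
        raise KeyError("persons table lacks an 'underreport_prob' column")
    keep = persons["underreport_prob"] < threshold
    logger.info("under-reporting restriction retains %.1f%% of persons",
                100 * keep.mean() if len(keep) else float("nan"))
    return persons.loc[keep].copy()
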