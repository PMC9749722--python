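"""Time-varying treatment-initiation model (the propensity score).

The monthly probability of starting the benefit is modelled as a
discrete-time hazard: a logistic regression of the initiation indicator
on baseline covariates plus a natural cubic spline of follow-up time,
fitted on each person's months up to and including the initiation month.
After initiation the probability of the observed (treated) state is 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .splines import natural_cubic_basis

DEFAULT_PERCENTILES = (5.0, 25.0, 50.0, 75.0, 95.0)


@dataclass
class SplineSpec:
    """Knot percentiles and their resolved locations in month units."""

    percentiles: tuple
    knots: np.ndarray

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if len(self.knots) < 3 or np.any(np.diff(self.knots) <= 0):
            raise ValueError("need >=3 strictly increasing knots "
                             "(>=2 interior after boundary knots)")

    def basis(self, t) -> np.ndarray:
        return natural_cubic_basis(t, self.knots)

    @property
    def n_columns(self) -> int:
        return len(self.knots) - 1


def resolve_knots(times, percentiles=DEFAULT_PERCENTILES) -> SplineSpec:
    """Knots at empirical percentiles (linear interpolation) of observed
    person-month times; duplicate knots are collapsed, with an error if
    fewer than 3 distinct locations remain."""
    t = np.asarray(times, dtype=float)
    if len(np.unique(t)) < 5:
        raise ValueError("need at least 5 distinct time values to place knots")
    knots = np.percentile(t, percentiles, method="linear")
    knots = np.unique(knots)
    if len(knots) < 3:
        raise ValueError("fewer than 3 distinct knots after collapsing duplicates")
    return SplineSpec(tuple(percentiles), knots)


@dataclass
class PSModel:
    """Fitted initiation-hazard model: coefficients, encoding, knots."""

    params: dict
    covariates: tuple
    encoding: dict  # categorical covariate -> list of levels (first = reference)
    spline: SplineSpec
    converged: bool
    n_rows: int
    n_initiations: int
    unseen_level_action: str = "error"

    def design(self, df: pd.DataFrame) -> pd.DataFrame:
        return build_design(df, self.covariates, self.spline, self.encoding,
                            self.unseen_level_action)

    def to_json(self, path: str | Path | None = None, **kw) -> str:
        d = {
            "params": self.params,
            "covariates": list(self.covariates),
            "encoding": self.encoding,
            "spline": {"percentiles": list(self.spline.percentiles),
                       "knots": self.spline.knots.tolist()},
            "converged": self.converged,
            "n_rows": self.n_rows,
            "n_initiations": self.n_initiations,
        }
        s = json.dumps(d, **kw)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, s: str) -> "PSModel":
        d = json.loads(s)
        spline = SplineSpec(tuple(d["spline"]["percentiles"]),
                            np.asarray(d["spline"]["knots"]))
        return cls(d["params"], tuple(d["covariates"]), d["encoding"], spline,
                   d["converged"], d["n_rows"], d["n_initiations"])


def _is_categorical(col: pd.Series) -> bool:
    return (isinstance(col.dtype, pd.CategoricalDtype)
            or col.dtype == object or str(col.dtype) == "string")


def build_design(df: pd.DataFrame, covariates, spline: SplineSpec | None,
                 encoding: dict | None = None,
                 unseen_level_action: str = "error"):
    """Design matrix: intercept, encoded covariates, spline basis of t.

    When ``encoding`` is None it is derived from the data (categorical
    columns one-hot encoded against their first level as reference) and
    returned alongside the matrix; otherwise the stored encoding is
    applied, with unseen levels raising an error by default or falling
    back to the reference level."""
    derive = encoding is None
    enc = {} if derive else encoding
    parts = {"intercept": np.ones(len(df))}
    for name in covariates:
        col = df[name]
        if derive:
            if _is_categorical(col):
                enc[name] = [str(l) for l in (
                    col.cat.categories if isinstance(col.dtype, pd.CategoricalDtype)
                    else sorted(col.dropna().unique()))]
        if name in enc:
            levels = enc[name]
            vals = col.astype(str)
            unseen = ~vals.isin(levels)
            if unseen.any():
                if unseen_level_action == "error":
                    raise ValueError(
                        f"unseen level(s) {sorted(vals[unseen].unique())} "
                        f"for covariate {name!r}")
                vals = vals.where(~unseen, levels[0])
            for lev in levels[1:]:
                parts[f"{name}[{lev}]"] = (vals == lev).to_numpy(dtype=float)
        else:
            parts[name] = col.to_numpy(dtype=float)
    if spline is not None:
        B = spline.basis(df["t"].to_numpy(dtype=float))
        for j in range(B.shape[1]):
            parts[f"spline_t_{j}"] = B[:, j]
    X = pd.DataFrame(parts, index=df.index)
    return (X, enc) if derive else X


def ps_fitting_rows(person_months: pd.DataFrame) -> pd.DataFrame:
    """Rows entering the initiation model: untreated months plus each
    person's in-window initiation month (outcome 1 there, 0 elsewhere).
    Persons already treated when their risk period starts contribute no
    fitting rows."""
    keep = (person_months["treated"] == 0) | person_months["initiation"]
    return person_months.loc[keep]


def fit_ps_model(person_months: pd.DataFrame, covariates=(),
                 percentiles=DEFAULT_PERCENTILES,
                 spline: SplineSpec | None = None) -> PSModel:
    """Maximum-likelihood logistic fit of monthly initiation.

    ``covariates`` may be empty, giving the covariate-free, time-only
    model used as the numerator of stabilized weights.
    """
    rows = ps_fitting_rows(person_months)
    y = rows["initiation"].to_numpy(dtype=float)
    n_init = int(y.sum())
    if n_init == 0:
        raise ValueError("no initiations observed; cannot fit initiation model")
    if spline is None:
        spline = resolve_knots(rows["t"].to_numpy(), percentiles)
    X, encoding = build_design(rows, covariates, spline)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    if not res.converged:
        raise RuntimeError("initiation model did not converge")
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError("non-finite coefficients (separation?)")
    model = PSModel(params=dict(zip(X.columns, map(float, res.params))),
                    covariates=tuple(covariates), encoding=encoding,
                    spline=spline, converged=bool(res.converged),
                    n_rows=len(rows), n_initiations=n_init)
    model._results = res  # fitted statsmodels results, kept for diagnostics
    return model


def predict_ps(model: PSModel, person_months: pd.DataFrame) -> np.ndarray:
    """Monthly initiation probability per row; exactly 1 after initiation.

    Pre-initiation rows (and the initiation month itself) get the model's
    expit(linear predictor); months already under treatment that are not
    the initiation month get probability 1, the convention for an
    absorbing exposure.
    """
    X = model.design(person_months)
    beta = np.array([model.params[c] for c in X.columns])
    p = expit(X.to_numpy() @ beta)
    post = (person_months["treated"].to_numpy() == 1) \
        & ~person_months["initiation"].to_numpy()
    p[post] = 1.0
    return p
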