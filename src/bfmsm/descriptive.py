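"""Descriptive surfaces: mortality rates and covariate balance.

Directly age-standardized rates use the classical weighted-Poisson
variance (each age band's event count treated as Poisson), the normal
approximation on the rate scale by default with a log-rate variant.
Standardized mean differences (SMDs) quantify covariate balance between
benefit recipients and non-recipients before weighting; multi-category
covariates use the Mahalanobis generalization so each covariate yields a
single number.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

PER = 100_000.0


def crude_rate(events: float, person_years: float) -> float:
    """Events per 100 000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return PER * events / person_years


@dataclass
class AgeSpecificCounts:
    """Events, person-years and standard-population weights per age band."""

    bands: Sequence[str]
    events: np.ndarray
    person_years: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        self.person_years = np.asarray(self.person_years, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if not (len(self.bands) == len(self.events) == len(self.person_years)
                == len(self.weights)):
            raise ValueError("age-band arrays must have equal length")
        if np.any(self.events < 0):
            raise ValueError("negative event count")
        if np.any((self.events > 0) & (self.person_years <= 0)):
            raise ValueError("band with events but no person-time")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("standard-population weights must sum to 1")


@dataclass
class StandardizedRate:
    rate: float
    lower: float
    upper: float

    def __post_init__(self):
        if not (0 <= self.lower <= self.rate <= self.upper):
            raise ValueError("confidence limits must bracket the rate")


def direct_standardized_rate(counts: AgeSpecificCounts, alpha: float = 0.05,
                             scale: str = "rate") -> StandardizedRate:
    """Directly standardized rate per 100 000 person-years with 95% CI.

    rate = Σ_a w_a d_a / n_a, var = Σ_a w_a² d_a / n_a² (Poisson counts),
    normal interval on the rate scale (default) or the log-rate scale.
    Empty bands (no person-time, no events) contribute nothing.
    """
    w, d, n = counts.weights, counts.events, counts.person_years
    ok = n > 0
    rate = float(np.sum(w[ok] * d[ok] / n[ok]))
    var = float(np.sum(w[ok] ** 2 * d[ok] / n[ok] ** 2))
    z = stats.norm.ppf(1 - alpha / 2)
    if scale == "rate":
        lo, hi = rate - z * np.sqrt(var), rate + z * np.sqrt(var)
    elif scale == "log":
        if rate <= 0:
            lo = hi = rate
        else:
            se_log = np.sqrt(var) / rate
            lo, hi = rate * np.exp(-z * se_log), rate * np.exp(z * se_log)
    else:
        raise ValueError("scale must be 'rate' or 'log'")
    return StandardizedRate(PER * rate, PER * max(0.0, lo), PER * hi)


def age_specific_counts(person_months: pd.DataFrame, band_width: int = 5,
                        standard: pd.Series | None = None) -> AgeSpecificCounts:
    """Aggregate person-months into age-band events / person-years.

    ``standard`` maps band labels to standard-population counts; by
    default the table's own person-year distribution is the standard
    (self-standardization), under which the standardized rate equals the
    crude rate.
    """
    age = person_months["age_years"].to_numpy()
    top = int(np.ceil((age.max() + 1e-9) / band_width) * band_width)
    edges = np.arange(0, top + band_width, band_width)
    labels = [f"{a}-{b - 1}" for a, b in zip(edges[:-1], edges[1:])]
    band = pd.cut(age, bins=edges, labels=labels, right=False)
    g = person_months.groupby(band, observed=False)
    events = g["event"].sum().to_numpy(dtype=float)
    pyr = (g.size() / 12.0).to_numpy(dtype=float)
    if standard is None:
        weights = pyr / pyr.sum()
    else:
        weights = np.array([standard.get(l, 0.0) for l in labels], dtype=float)
        weights = weights / weights.sum()
    return AgeSpecificCounts(labels, events, pyr, weights)


def read_standard_population(path) -> pd.Series:
    """Two-column delimited file: age-band label, population count."""
    df = pd.read_csv(path, header=None, names=["band", "population"])
    return df.set_index("band")["population"].astype(float)


# -- standardized mean differences -------------------------------------------

def smd(group_a, group_b, kind: str = "binary") -> float:
    """Standardized mean difference between two groups.

    binary      : ``(count, total)`` per group
    continuous  : ``(mean, sd)`` per group
    categorical : proportion (or count) vectors per group; uses the
                  Mahalanobis form over K−1 levels with the averaged
                  multinomial covariance
    """
    if kind == "binary":
        c1, n1 = group_a
        c2, n2 = group_b
        p1, p2 = c1 / n1, c2 / n2
        pooled = (p1 * (1 - p1) + p2 * (1 - p2)) / 2
        if pooled == 0:
            if p1 != p2:
                raise ValueError("zero pooled variance with unequal proportions")
            return 0.0
        return abs(p1 - p2) / np.sqrt(pooled)
    if kind == "continuous":
        m1, s1 = group_a
        m2, s2 = group_b
        pooled = (s1 ** 2 + s2 ** 2) / 2
        if pooled == 0:
            if m1 != m2:
                raise ValueError("zero pooled variance with unequal means")
            return 0.0
        return abs(m1 - m2) / np.sqrt(pooled)
    if kind == "categorical":
        p1 = np.asarray(group_a, dtype=float)
        p2 = np.asarray(group_b, dtype=float)
        p1, p2 = p1 / p1.sum(), p2 / p2.sum()
        diff = (p1 - p2)[:-1]
        if np.allclose(diff, 0):
            return 0.0

        def cov(p):
            q = p[:-1]
            return np.diag(q) - np.outer(q, q)

        s = (cov(p1) + cov(p2)) / 2
        return float(np.sqrt(diff @ np.linalg.solve(s, diff)))
    raise ValueError(f"unknown covariate kind {kind!r}")


def balance_table(persons: pd.DataFrame, group_col: str,
                  covariates: dict[str, str]) -> pd.DataFrame:
    """Per-covariate SMD between the two levels of ``group_col``.

    ``covariates`` maps column name to kind ('binary', 'categorical',
    'continuous'). Missing values are excluded from each covariate's
    denominators.
    """
    flag = persons[group_col].astype(bool)
    rows = []
    for name, kind in covariates.items():
        if name not in persons.columns:
            raise KeyError(f"covariate {name!r} not in table")
        col = persons[name]
        a, b = col[~flag].dropna(), col[flag].dropna()
        if kind == "binary":
            value = smd((a.astype(bool).sum(), len(a)),
                        (b.astype(bool).sum(), len(b)), "binary")
        elif kind == "continuous":
            value = smd((a.mean(), a.std()), (b.mean(), b.std()), "continuous")
        else:
            levels = sorted(set(a.unique()) | set(b.unique()))
            value = smd(a.value_counts().reindex(levels, fill_value=0).to_numpy(),
                        b.value_counts().reindex(levels, fill_value=0).to_numpy(),
                        "categorical")
        rows.append({"covariate": name, "kind": kind, "smd": value,
                     "n_non_recipient": len(a), "n_recipient": len(b)})
    return pd.DataFrame(rows)
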