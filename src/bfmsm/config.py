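"""Configuration for the synthetic open-cohort generator.

The generator emulates a registry-based natural experiment: individuals
enter a social-programme registry on a rolling basis, may start receiving
a cash-transfer benefit (an absorbing, staggered exposure) with a monthly
hazard that depends on their baseline characteristics and on time since
registration, and may die with a monthly hazard that depends on the same
characteristics, on municipality deprivation and on current benefit
receipt. Deaths may go unregistered with a municipality-specific
probability, in which case the person appears administratively censored.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: death-cause classes; the first three together form the CVD outcome
CAUSE_LEVELS = ("ihd", "cerebrovascular", "other_cvd", "non_cvd")
CVD_CAUSES = frozenset({"ihd", "cerebrovascular", "other_cvd"})

#: yearly per-capita income eligibility thresholds (BRL/month) used to
#: standardize incomes recorded in different application years
DEFAULT_THRESHOLD_TABLE = {2011: 70.0, 2012: 70.0, 2013: 70.0, 2014: 77.0, 2015: 77.0}


@dataclass(frozen=True)
class Confounder:
    """One baseline covariate and its effects on the two monthly logits.

    Parameters
    ----------
    name : str
        Column name, unique within a config.
    kind : {'binary', 'categorical', 'continuous'}
    dist : tuple
        Marginal distribution: ``(p,)`` for binary, ``(levels, probs)``
        for categorical, ``(mean, sd)`` for continuous (normal).
    uptake_beta, mortality_beta : float or tuple
        Additive effect on the treatment-initiation / mortality logit.
        For categorical covariates a tuple aligned with ``levels`` (the
        first level is conventionally the reference with effect 0).
    """

    name: str
    kind: str
    dist: tuple
    uptake_beta: float | tuple = 0.0
    mortality_beta: float | tuple = 0.0

    def __post_init__(self):
        if self.kind not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "binary":
            (p,) = self.dist
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: binary probability {p} outside [0,1]")
        elif self.kind == "categorical":
            levels, probs = self.dist
            if len(levels) != len(probs) or len(levels) < 2:
                raise ValueError(f"{self.name}: levels/probs mismatch")
            if not math.isclose(sum(probs), 1.0, abs_tol=1e-9):
                raise ValueError(f"{self.name}: category probabilities must sum to 1")
            for beta in (self.uptake_beta, self.mortality_beta):
                if len(tuple(np.atleast_1d(beta))) not in (1, len(levels)):
                    raise ValueError(f"{self.name}: effect vector length mismatch")
        else:
            mean, sd = self.dist
            if sd < 0:
                raise ValueError(f"{self.name}: negative sd")


@dataclass
class SimulationConfig:
    """Full data-generating specification with known ground truth.

    Time is discrete in months. ``admin_end`` is the exclusive calendar
    end of follow-up: observable months are ``0 .. admin_end - 1``.
    """

    n_persons: int
    seed: int = 0
    horizon_months: int = 60
    admin_end: int = 60
    true_log_hr: float = math.log(0.8)
    true_log_hr_by_quintile: tuple | None = None  # overrides true_log_hr per stratum
    confounder_spec: tuple = ()
    baseline_uptake_logit: float = -3.66  # ~2.5%/month initiation hazard
    baseline_mortality_logit: float = -6.21  # ~0.2%/month death hazard
    uptake_time_trend: tuple = (-0.015,)  # polynomial coefficients on t, t^2, ...
    n_municipalities: int = 200
    deprivation_effect_on_mortality: float = 0.10  # per quintile step, centred at q3
    deprivation_effect_on_uptake: float = 0.0
    underreporting_prob: float | tuple | Mapping = 0.0
    entry_age_distribution: tuple = ("uniform", 25.0, 70.0)
    income_distribution: tuple = ("uniform", 0.0, 330.0)
    excluded_ethnicity_prob: float = 0.015
    cause_probs: tuple = (("ihd", 0.0699), ("cerebrovascular", 0.0629),
                          ("other_cvd", 0.0862), ("non_cvd", 0.7810))
    start_year: int = 2011
    staggered_entry: bool = True

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ValueError("n_persons must be non-negative")
        if self.horizon_months < 1:
            raise ValueError("horizon_months must be >= 1")
        if self.admin_end < 1:
            raise ValueError("admin_end must be >= 1")
        if self.n_municipalities < 1:
            raise ValueError("n_municipalities must be >= 1")
        for x in (self.baseline_uptake_logit, self.baseline_mortality_logit,
                  self.true_log_hr):
            if not math.isfinite(x):
                raise ValueError(f"non-finite logit parameter: {x}")
        if self.true_log_hr_by_quintile is not None:
            if len(self.true_log_hr_by_quintile) != 5:
                raise ValueError("true_log_hr_by_quintile needs 5 values")
            if not all(math.isfinite(x) for x in self.true_log_hr_by_quintile):
                raise ValueError("non-finite stratum effect")
        names = [c.name for c in self.confounder_spec]
        if len(set(names)) != len(names):
            raise ValueError("confounder names must be unique")
        up = self.resolve_underreporting()
        if np.any((up < 0) | (up > 1)):
            raise ValueError("under-reporting probabilities must lie in [0,1]")
        if not math.isclose(sum(p for _, p in self.cause_probs), 1.0, abs_tol=1e-9):
            raise ValueError("cause probabilities must sum to 1")

    def resolve_underreporting(self) -> np.ndarray:
        """Per-municipality under-reporting probabilities as an array."""
        u = self.underreporting_prob
        if isinstance(u, Mapping):
            arr = np.zeros(self.n_municipalities)
            for k, v in u.items():
                arr[int(k)] = v
            return arr
        if np.isscalar(u):
            return np.full(self.n_municipalities, float(u))
        arr = np.asarray(u, dtype=float)
        if arr.shape != (self.n_municipalities,):
            raise ValueError("underreporting_prob length must equal n_municipalities")
        return arr

    # -- JSON round-trip (sidecar files, CLI) --------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["confounder_spec"] = [dataclasses.asdict(c) for c in self.confounder_spec]
        u = self.underreporting_prob
        if not np.isscalar(u) and not isinstance(u, Mapping):
            d["underreporting_prob"] = list(map(float, u))
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        spec = []
        for c in d.get("confounder_spec", ()):
            c = dict(c)
            if c["kind"] == "categorical":
                levels, probs = c["dist"]
                c["dist"] = (tuple(levels), tuple(probs))
            else:
                c["dist"] = tuple(c["dist"])
            for k in ("uptake_beta", "mortality_beta"):
                if isinstance(c[k], (list, tuple)):
                    c[k] = tuple(c[k])
            spec.append(Confounder(**c))
        d["confounder_spec"] = tuple(spec)
        for k in ("uptake_time_trend", "entry_age_distribution", "income_distribution"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        if "cause_probs" in d:
            d["cause_probs"] = tuple((str(a), float(b)) for a, b in d["cause_probs"])
        if isinstance(d.get("underreporting_prob"), list):
            d["underreporting_prob"] = tuple(d["underreporting_prob"])
        return cls(**d)

    @classmethod
    def from_json(cls, s: str) -> "SimulationConfig":
        return cls.from_dict(json.loads(s))


def default_confounders() -> tuple:
    """Standard confounder set: one binary, one 3-level categorical, one
    continuous covariate, each raising both benefit uptake and mortality
    so that naive and causal hazard ratios differ materially."""
    return (
        Confounder("male", "binary", (0.49,), uptake_beta=0.10, mortality_beta=0.30),
        Confounder("education", "categorical",
                   (("high", "medium", "low"), (0.35, 0.40, 0.25)),
                   uptake_beta=(0.0, 0.3, 0.6), mortality_beta=(0.0, 0.25, 0.5)),
        Confounder("income_z", "continuous", (0.0, 1.0),
                   uptake_beta=-0.35, mortality_beta=-0.25),
    )


def default_config(n_persons: int, seed: int = 0, **overrides) -> SimulationConfig:
    """The study conditions used throughout: confounded monthly uptake,
    a protective treatment effect (HR 0.8 conditional), five years of
    rolling registration with administrative censoring."""
    cfg = SimulationConfig(n_persons=n_persons, seed=seed,
                           confounder_spec=default_confounders())
    return dataclasses.replace(cfg, **overrides) if overrides else cfg


def underreporting_scenario_config(n_persons: int, seed: int = 0) -> SimulationConfig:
    """Scenario with death under-reporting concentrated where uptake is high.

    Municipalities in the two most deprived quintiles fail to register
    half of their deaths, and deprivation strongly raises benefit uptake
    while leaving true mortality untouched (and the true effect is null),
    so the only distortion of the estimated hazard ratio is the
    differential masking of deaths among the treated. Restricting to
    municipalities with near-zero under-reporting removes it.
    """
    n_mun = 200
    # quintile layout must match simulate_cohort's rank-based assignment
    quintile = 1 + (5 * np.arange(n_mun)) // n_mun
    under = np.where(quintile >= 4, 0.5, 0.0)
    return SimulationConfig(
        n_persons=n_persons,
        seed=seed,
        true_log_hr=0.0,
        confounder_spec=default_confounders(),
        baseline_uptake_logit=-3.0,
        baseline_mortality_logit=-5.3,
        n_municipalities=n_mun,
        deprivation_effect_on_mortality=0.0,
        deprivation_effect_on_uptake=0.5,
        underreporting_prob=tuple(under),
    )
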