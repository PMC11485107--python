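"""Synthetic ACS-like cohort generator.

Emulates the marginal, class-conditional structure of a real acute
coronary syndrome admission cohort: ~10% six-month mortality, and per
outcome class the observed means/IQRs of age, systolic blood pressure,
heart rate, troponin, maximum creatinine, the STEMI proportion and the
Killip-class distribution.

Distribution families follow the shape of the published summaries:
age/SBP/heart rate are Gaussian (sd = IQR / 1.349); troponin and
creatinine are heavily right-skewed (their means sit near or above the
75th percentile) and are modelled log-normally, with (mu, sigma) fitted
by least squares on the relative errors of mean, Q1 and Q3 — the three
published summaries are not jointly attainable by any log-normal, so the
fit is a documented compromise.  Features are independent given the
class; a Gaussian-copula mode adds within-class rank correlation when a
correlation matrix is supplied.

Cardiac arrest (needed by the GRACE score, not summarized in the source
cohort) is generated as a rare binary (2% survivors / 10% deaths) and is
explicitly uncalibrated, as is the sex split (70% male).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import Cohort, FeatureSpec
from .rules import Rule, apply_ruleset

__all__ = [
    "ClassConditional",
    "GeneratorConfig",
    "PlantedRuleConfig",
    "default_config",
    "generate_cohort",
    "plant_rule_outcomes",
]


@dataclass(frozen=True)
class ClassConditional:
    """One feature's distribution for one outcome class.

    family: "normal" (loc, scale), "lognormal" (fitted to mean/q1/q3),
    "bernoulli" (p), or "categorical" (values + weights).
    """

    family: str
    params: tuple = ()
    clip: tuple[float, float] | None = None

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "normal":
            loc, scale = self.params
            out = rng.normal(loc, scale, n)
        elif self.family == "lognormal":
            mu, sigma = _fit_lognormal(*self.params)
            out = rng.lognormal(mu, sigma, n)
        elif self.family == "bernoulli":
            (p,) = self.params
            out = rng.binomial(1, p, n).astype(float)
        elif self.family == "categorical":
            values, weights = self.params
            out = rng.choice(np.asarray(values, dtype=float), size=n, p=list(weights))
        else:
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.clip is not None:
            out = np.clip(out, *self.clip)
        return out

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Quantile function, used by the Gaussian-copula mode."""
        if self.family == "normal":
            out = stats.norm.ppf(u, *self.params)
        elif self.family == "lognormal":
            mu, sigma = _fit_lognormal(*self.params)
            out = stats.lognorm.ppf(u, sigma, scale=np.exp(mu))
        elif self.family == "bernoulli":
            (p,) = self.params
            out = (u > 1 - p).astype(float)
        elif self.family == "categorical":
            values, weights = self.params
            edges = np.cumsum(weights)
            out = np.asarray(values, dtype=float)[np.searchsorted(edges, u, side="right").clip(0, len(weights) - 1)]
        else:
            raise ValueError(self.family)
        if self.clip is not None:
            out = np.clip(out, *self.clip)
        return out


@lru_cache(maxsize=None)
def _fit_lognormal(mean: float, q1: float, q3: float) -> tuple[float, float]:
    """Least-squares (mu, sigma) matching mean and quartiles in relative error."""
    z = stats.norm.ppf(0.75)

    def loss(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        m = np.exp(mu + sigma**2 / 2)
        lo, hi = np.exp(mu - z * sigma), np.exp(mu + z * sigma)
        return ((m - mean) / mean) ** 2 + ((lo - q1) / q1) ** 2 + ((hi - q3) / q3) ** 2

    # moment-style start: median near geometric mean of the quartiles
    mu0 = 0.5 * (np.log(q1) + np.log(q3))
    s0 = max((np.log(q3) - np.log(q1)) / (2 * z), 0.1)
    res = optimize.minimize(loss, [mu0, np.log(s0)], method="Nelder-Mead")
    mu, log_sigma = res.x
    return float(mu), float(np.exp(log_sigma))


@dataclass
class GeneratorConfig:
    """Cohort size, mortality prevalence and per-class feature distributions."""

    n: int = 1469
    prevalence: float = 150 / 1469
    features: dict[str, dict[int, ClassConditional]] = field(default_factory=dict)
    p_male: float = 0.7
    copula_corr: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if not self.features:
            self.features = default_feature_distributions()


def default_feature_distributions() -> dict[str, dict[int, ClassConditional]]:
    """Class-conditional defaults mirroring the study cohort's summaries.

    Keyed by feature, then outcome class (0 survival, 1 death).  Killip
    weights are chosen so the class means are 1.35 and 2.53.
    """
    kl = (1, 2, 3, 4)
    return {
        "age": {
            0: ClassConditional("normal", (66.87, (77 - 57) / 1.349), clip=(18, 110)),
            1: ClassConditional("normal", (77.49, (83 - 74) / 1.349), clip=(18, 110)),
        },
        "sbp": {
            0: ClassConditional("normal", (135.05, (150.0 - 119.5) / 1.349), clip=(50, 260)),
            1: ClassConditional("normal", (123.07, (140.75 - 104.25) / 1.349), clip=(50, 260)),
        },
        "heart_rate": {
            0: ClassConditional("normal", (75.73, (85 - 64) / 1.349), clip=(30, 250)),
            1: ClassConditional("normal", (84.02, (90 - 70) / 1.349), clip=(30, 250)),
        },
        "troponin": {
            0: ClassConditional("lognormal", (41.54, 1.03, 39.50), clip=(0.01, 5000)),
            1: ClassConditional("lognormal", (60.46, 3.78, 48.80), clip=(0.01, 5000)),
        },
        "creatinine": {  # umol/L; GRACE converts to mg/dl downstream
            0: ClassConditional("lognormal", (112.28, 78.0, 111.6), clip=(20, 2000)),
            1: ClassConditional("lognormal", (194.77, 96.0, 207.75), clip=(20, 2000)),
        },
        "stemi": {
            0: ClassConditional("bernoulli", (0.36,)),
            1: ClassConditional("bernoulli", (0.46,)),
        },
        "killip": {
            0: ClassConditional("categorical", (kl, (0.75, 0.17, 0.06, 0.02))),
            1: ClassConditional("categorical", (kl, (0.25, 0.25, 0.22, 0.28))),
        },
        "cardiac_arrest": {  # uncalibrated: absent from the source summaries
            0: ClassConditional("bernoulli", (0.02,)),
            1: ClassConditional("bernoulli", (0.10,)),
        },
    }


_KINDS = {
    "stemi": "binary",
    "cardiac_arrest": "binary",
    "killip": "ordinal",
}
_UNITS = {
    "age": "years", "sbp": "mmHg", "heart_rate": "bpm",
    "troponin": "ng/L", "creatinine": "umol/L",
}


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> Cohort:
    """Draw a synthetic cohort; a pure function of (config, seed)."""
    config = config or GeneratorConfig()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    y = rng.binomial(1, config.prevalence, config.n)
    names = list(config.features)
    data = np.empty((config.n, len(names)))
    for cls in (0, 1):
        mask = y == cls
        n_cls = int(mask.sum())
        if n_cls == 0:
            continue
        if config.copula_corr is not None:
            L = np.linalg.cholesky(np.asarray(config.copula_corr))
            z = rng.standard_normal((n_cls, len(names))) @ L.T
            u = stats.norm.cdf(z)
            for j, name in enumerate(names):
                data[mask, j] = config.features[name][cls].ppf(u[:, j])
        else:
            for j, name in enumerate(names):
                data[mask, j] = config.features[name][cls].sample(n_cls, rng)
    X = pd.DataFrame(data, columns=names)
    for name in names:
        if _KINDS.get(name) in ("binary", "ordinal"):
            X[name] = X[name].astype(int)
    schema = [
        FeatureSpec(
            name,
            _KINDS.get(name, "numeric"),
            _UNITS.get(name, ""),
            sex_specific=name == "creatinine",
            categories=(1, 2, 3, 4) if name == "killip" else None,
        )
        for name in names
    ]
    sex = np.where(rng.random(config.n) < config.p_male, "M", "F")
    return Cohort(X, y, schema, sex)


@dataclass(frozen=True)
class PlantedRuleConfig:
    """Ground-truth rule(s) plus label-flip noise for recovery experiments."""

    rules: tuple[Rule, ...]
    noise: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.rules) == 0:
            raise ValueError("at least one generating rule is required")
        if not 0 <= self.noise < 0.5:
            raise ValueError("noise must lie in [0, 0.5)")


def plant_rule_outcomes(cohort: Cohort, config: PlantedRuleConfig) -> Cohort:
    """Replace outcomes by the rules' prediction (death if any rule fires),
    each label flipped independently with probability ``config.noise``."""
    rng = np.random.default_rng(config.seed)
    T = apply_ruleset(config.rules, cohort.X)
    y = (T == 1).any(axis=1).astype(int)
    flips = rng.random(cohort.n) < config.noise
    y = np.where(flips, 1 - y, y)
    return Cohort(cohort.X.copy(), y, cohort.schema, cohort.sex)
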