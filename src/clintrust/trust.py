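"""Quantitative trust metrics for binary risk models.

Three complementary perspectives are quantified:

* **Robustness** — a stability measure on [-1, 1]: for an instance x with
  neighbor set S split into same-model-label neighbors S+ and
  opposite-label neighbors S-,

      S_t(x | S+, S-) = [ sum_{i in S+} exp(-d_i^2 / (2 sigma^2))
                        - sum_{j in S-} exp(-d_j^2 / (2 sigma^2)) ] / k

  with d the Euclidean distance, k = |S+| + |S-| and sigma the *mean*
  distance from x to its k neighbors.  Positive values mean nearby
  instances tend to receive the same label.  The global stability of a
  model is the average over all instances, each compared against every
  other instance (k = N - 1).  Labels are model predictions, not true
  outcomes: stability measures the model's consistency, not its accuracy.

* **Confidence** — a nonparametric bootstrap 95% CI of the geometric mean
  of sensitivity and specificity.  Resampling is stratified by the true
  outcome so SE and SP are defined in every resample; a narrower interval
  means a more precise performance estimate.

* **Interpretability** — exact interventional Shapley values per feature,
  aggregated to a ranking by mean |phi|, compared with a clinical
  reference ranking through Spearman rank correlation.

Degenerate cases: sigma = 0 (all neighbors coincide with x) assigns kernel
weight 1 to every neighbor, the continuous limit of the Gaussian kernel —
so a duplicate-only neighborhood of same-label points scores exactly +1.
Note that for k neighbors at *positive* common distance the same-label
score is exp(-1/2) (about 0.607), not 1: the kernel discounts distance.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, zscore_normalize

__all__ = [
    "Neighborhood",
    "StabilityResult",
    "GmeanCI",
    "ShapleyAttribution",
    "FeatureRanking",
    "TrustReport",
    "instance_stability",
    "global_stability",
    "gmean_bootstrap_ci",
    "exact_shapley",
    "rank_features",
    "shapley_ranking",
    "spearman_rho",
    "trust_report",
]


@dataclass(frozen=True)
class Neighborhood:
    """An instance's neighbors, split by agreement with its label.

    ``d_same``/``d_diff`` are Euclidean distances from x to the neighbors
    whose label matches / opposes the label of x.  ``sigma`` is the mean of
    all k distances.
    """

    d_same: np.ndarray
    d_diff: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "d_same", np.asarray(self.d_same, dtype=float))
        object.__setattr__(self, "d_diff", np.asarray(self.d_diff, dtype=float))
        if self.k < 1:
            raise ValueError("neighborhood must contain at least one neighbor")
        if (self.d_same < 0).any() or (self.d_diff < 0).any():
            raise ValueError("distances must be nonnegative")

    @property
    def k(self) -> int:
        return len(self.d_same) + len(self.d_diff)

    @property
    def sigma(self) -> float:
        return float(np.concatenate([self.d_same, self.d_diff]).mean())

    @classmethod
    def from_points(
        cls, x: np.ndarray, same: np.ndarray, diff: np.ndarray
    ) -> "Neighborhood":
        """Build from coordinates: x (M,), same (n+, M), diff (n-, M)."""
        x = np.asarray(x, dtype=float)
        same = np.asarray(same, dtype=float).reshape(-1, len(x))
        diff = np.asarray(diff, dtype=float).reshape(-1, len(x))
        return cls(
            np.linalg.norm(same - x, axis=1),
            np.linalg.norm(diff - x, axis=1),
        )


def _kernel(d: np.ndarray, sigma: float) -> np.ndarray:
    if sigma == 0.0:
        # all neighbors coincide with x; continuous limit of the kernel
        return np.ones_like(d)
    r = d / sigma  # ratio form is robust when sigma is subnormal
    return np.exp(-0.5 * r * r)


def instance_stability(neighborhood: Neighborhood) -> float:
    """Kernel-weighted label agreement for one instance, in [-1, 1]."""
    sigma = neighborhood.sigma
    plus = _kernel(neighborhood.d_same, sigma).sum()
    minus = _kernel(neighborhood.d_diff, sigma).sum()
    return float((plus - minus) / neighborhood.k)


@dataclass(frozen=True)
class StabilityResult:
    """Per-instance stability values and their cohort mean."""

    per_instance: np.ndarray
    global_value: float

    def __post_init__(self) -> None:
        v = np.asarray(self.per_instance, dtype=float)
        object.__setattr__(self, "per_instance", v)
        if (np.abs(v) > 1 + 1e-12).any():
            raise ValueError("stability values must lie in [-1, 1]")


def global_stability(
    predict: Callable[[pd.DataFrame], np.ndarray],
    cohort: Cohort,
    k: int | None = None,
    normalize: bool = True,
) -> StabilityResult:
    """Mean instance stability of a model's predictions over a cohort.

    Every other instance is a neighbor (k = N - 1) unless ``k`` restricts
    to the k nearest.  Distances are Euclidean on z-scored numeric features
    (binary features enter as 0/1) so that mixed-scale clinical variables
    contribute comparably.
    """
    if cohort.n < 2:
        raise ValueError("stability needs at least two instances")
    labels = np.asarray(predict(cohort.X)).astype(int)
    if normalize:
        numeric = [s.name for s in cohort.schema if s.kind == "numeric"
                   and cohort.X[s.name].nunique() > 1]
        Z = zscore_normalize(cohort, numeric)[0].values() if numeric else cohort.values()
    else:
        Z = cohort.values()
    # pairwise distances; N is at most a few thousand in this setting
    sq = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1) if cohort.n <= 600 else None
    if sq is None:
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(Z))
    else:
        D = np.sqrt(sq)
    values = np.empty(cohort.n)
    for i in range(cohort.n):
        d = np.delete(D[i], i)
        lab = np.delete(labels, i)
        if k is not None and k < len(d):
            idx = np.argsort(d, kind="stable")[:k]
            d, lab = d[idx], lab[idx]
        nb = Neighborhood(d[lab == labels[i]], d[lab != labels[i]])
        values[i] = instance_stability(nb)
    return StabilityResult(values, float(values.mean()))


@dataclass(frozen=True)
class GmeanCI:
    """Percentile bootstrap CI of the geometric mean of SE and SP."""

    lower: float
    upper: float
    B: int
    alpha: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ValueError("CI bounds must satisfy 0 <= lower <= upper <= 1")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _gmean_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos, neg = y_true == 1, y_true == 0
    se = (y_pred[pos] == 1).mean()
    sp = (y_pred[neg] == 0).mean()
    return math.sqrt(se * sp)


def gmean_bootstrap_ci(
    y_true: Sequence[int],
    y_pred: Sequence[int],
    B: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> GmeanCI:
    """Stratified paired bootstrap percentile CI for G_mean.

    (y_true, y_pred) pairs are resampled with replacement *within* each
    true-outcome stratum, which keeps both sensitivity and specificity
    defined in every resample.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if B < 100:
        raise ValueError("B must be at least 100")
    strata = [np.flatnonzero(y_true == c) for c in (0, 1)]
    if any(len(s) == 0 for s in strata):
        raise ValueError("y_true must contain both classes")
    rng = np.random.default_rng(seed)
    gs = np.empty(B)
    for b in range(B):
        idx = np.concatenate([rng.choice(s, size=len(s), replace=True) for s in strata])
        gs[b] = _gmean_from_labels(y_true[idx], y_pred[idx])
    lo, hi = np.quantile(gs, [alpha / 2, 1 - alpha / 2])
    return GmeanCI(float(lo), float(hi), B, alpha, seed)


@dataclass(frozen=True)
class ShapleyAttribution:
    """Exact interventional Shapley values.

    ``phi`` is (n_instances, M); ``base_value`` the mean model output over
    the background set.  Efficiency holds exactly: for every instance,
    ``phi.sum() + base_value`` equals the model output on that instance.
    """

    phi: np.ndarray
    base_value: float
    feature_names: tuple[str, ...]


def exact_shapley(
    predict: Callable[[pd.DataFrame], np.ndarray],
    instances: pd.DataFrame,
    background: pd.DataFrame,
    max_features: int = 15,
) -> ShapleyAttribution:
    """Exact Shapley attribution by coalition enumeration.

    The value of a feature coalition S for instance x is the mean model
    output with features in S pinned to x and the rest drawn from the
    background rows (the interventional expectation).  phi is the
    Shapley-weighted average of marginal contributions over all
    2^(M-1) coalitions per feature.  Cost grows as 2^M model calls, hence
    the ``max_features`` guard; beyond it, use a sampling approximation.
    """
    features = list(instances.columns)
    M = len(features)
    if M > max_features:
        raise ValueError(
            f"{M} features exceeds the exact-enumeration limit {max_features}; "
            "use a sampling approximation"
        )
    if len(background) == 0:
        raise ValueError("background set must be nonempty")
    bg = background[features].to_numpy(dtype=float)
    Xs = instances[features].to_numpy(dtype=float)
    n_bg = len(bg)

    # v[mask] = mean_b f(x_S, b_{-S}) for every coalition bitmask, per instance
    n_inst = len(Xs)
    fact = [math.factorial(i) for i in range(M + 1)]
    phi = np.zeros((n_inst, M))
    v = np.empty((1 << M, n_inst))
    for mask in range(1 << M):
        synth = np.repeat(bg[None, :, :], n_inst, axis=0).reshape(n_inst * n_bg, M)
        for j in range(M):
            if mask >> j & 1:
                synth[:, j] = np.repeat(Xs[:, j], n_bg)
        out = np.asarray(
            predict(pd.DataFrame(synth, columns=features)), dtype=float
        ).reshape(n_inst, n_bg)
        v[mask] = out.mean(axis=1)
    for j in range(M):
        others = [i for i in range(M) if i != j]
        for r in range(M):
            w = fact[r] * fact[M - r - 1] / fact[M]
            for S in itertools.combinations(others, r):
                mask = sum(1 << i for i in S)
                phi[:, j] += w * (v[mask | (1 << j)] - v[mask])
    return ShapleyAttribution(phi, float(v[0].mean()), tuple(features))


@dataclass(frozen=True)
class FeatureRanking:
    """1-based importance ranks (1 = most important), ties averaged."""

    ranks: dict[str, float]

    @classmethod
    def from_importances(cls, importances: dict[str, float]) -> "FeatureRanking":
        names = list(importances)
        vals = np.array([importances[n] for n in names], dtype=float)
        r = stats.rankdata(-vals, method="average")
        return cls(dict(zip(names, r.tolist())))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureRanking":
        return cls({k: float(v) for k, v in json.loads(Path(path).read_text()).items()})


def rank_features(attr: ShapleyAttribution) -> FeatureRanking:
    """Rank features by mean |phi| across the attributed instances."""
    imp = np.abs(attr.phi).mean(axis=0)
    return FeatureRanking.from_importances(dict(zip(attr.feature_names, imp)))


def spearman_rho(rank_a: FeatureRanking, rank_b: FeatureRanking) -> float:
    """Spearman correlation between two rankings over the same feature set."""
    if set(rank_a.ranks) != set(rank_b.ranks):
        raise ValueError("rankings cover different feature sets")
    names = sorted(rank_a.ranks)
    if len(names) < 2:
        raise ValueError("need at least two features")
    a = [rank_a.ranks[n] for n in names]
    b = [rank_b.ranks[n] for n in names]
    return float(stats.spearmanr(a, b).statistic)


@dataclass
class TrustReport:
    """One model's trust row: stability, G_mean CI (+ width), Spearman rho."""

    stability: float
    stability_std: float
    gmean_ci: GmeanCI
    spearman: float
    model: str = ""
    ranking: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "stability": self.stability,
            "stability_std": self.stability_std,
            "gmean_ci": [self.gmean_ci.lower, self.gmean_ci.upper],
            "ci_width_pct": 100 * self.gmean_ci.width,
            "spearman_rho": self.spearman,
            "ranking": self.ranking,
            "bootstrap": {"B": self.gmean_ci.B, "alpha": self.gmean_ci.alpha,
                          "seed": self.gmean_ci.seed},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrustReport":
        d = json.loads(Path(path).read_text())
        ci = GmeanCI(d["gmean_ci"][0], d["gmean_ci"][1], d["bootstrap"]["B"],
                     d["bootstrap"]["alpha"], d["bootstrap"]["seed"])
        return cls(d["stability"], d["stability_std"], ci, d["spearman_rho"],
                   d["model"], d.get("ranking", {}))


def _score_fn(model) -> Callable[[pd.DataFrame], np.ndarray]:
    """Real-valued model output: decision scores when available, else labels."""
    if hasattr(model, "decision_function"):
        return lambda X: np.asarray(model.decision_function(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return lambda X: np.asarray(model.predict_proba(X))[:, 1]
    return lambda X: np.asarray(model.predict(X), dtype=float)


def shapley_ranking(
    model,
    cohort: Cohort,
    seed: int | None = None,
    n_instances: int = 50,
    n_background: int = 50,
) -> FeatureRanking:
    """Model feature ranking by mean |phi| over a seeded cohort subsample.

    The subsample is a pure function of (cohort, seed, sizes), so two
    models ranked with the same arguments are attributed on identical
    instances — in particular a model compared against its own ranking
    yields Spearman rho of exactly 1.
    """
    rng = np.random.default_rng(seed)
    inst = cohort.X.iloc[rng.choice(cohort.n, min(n_instances, cohort.n), replace=False)]
    bg = cohort.X.iloc[rng.choice(cohort.n, min(n_background, cohort.n), replace=False)]
    attr = exact_shapley(_score_fn(model), inst, bg)
    return rank_features(attr)


def trust_report(
    model,
    cohort: Cohort,
    reference_rank: FeatureRanking,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
    shap_instances: int = 50,
    shap_background: int = 50,
    name: str = "",
) -> TrustReport:
    """Assemble the full trust row for one fitted model on one cohort.

    Shapley attribution uses the model's decision scores when available
    (``decision_function`` / ``predict_proba``), else hard labels, over a
    seeded subsample of instances and background rows.  ``stability_std``
    is the per-instance dispersion within this cohort.
    """
    stab = global_stability(model.predict, cohort)
    ci = gmean_bootstrap_ci(cohort.y, model.predict(cohort.X), B=B, alpha=alpha,
                            seed=seed)
    ranking = shapley_ranking(model, cohort, seed, shap_instances, shap_background)
    # features the model never uses still get (tied, bottom) ranks via
    # their zero importance, so the correlation covers the full list
    rho = spearman_rho(ranking, reference_rank)
    return TrustReport(stab.global_value, float(stab.per_instance.std(ddof=0)),
                       ci, rho, name, ranking.ranks)
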