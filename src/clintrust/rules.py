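"""Rule-based mortality-risk classifier.

The model mimics a physician's reasoning in three stages:

1. a set of simple binary clinical rules (``if Killip = 4 then death``)
   derived from data and clinical knowledge;
2. a learned *correctness* model that, given a patient's risk factors,
   predicts which rules are reliable for that particular patient (the
   training target is the N x K correctness matrix R, where ``r_ik = 1``
   iff rule k's prediction matches patient i's true outcome);
3. risk aggregation over the accepted rules only: the mortality score is
   the fraction of accepted rules that predict death,
   ``t_i = (1/Q) * sum_j r_ij * t_ij``, thresholded at 0.5 (inclusive) for
   the final label.

A rule whose antecedent does not hold predicts survival (0); this
complement convention is what makes correctness well defined for
non-firing rules (a rule "albumin <= 25 -> death" is *correct* for a
patient with albumin 30 who survived).

The default correctness learner is binary relevance: one independent
L2-regularized logistic classifier per rule, probabilities thresholded at
0.5.  Any estimator following the same contract can be swapped in.
"""

from __future__ import annotations

import json
import operator
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import balanced_accuracy_score
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort

__all__ = [
    "Rule",
    "RuleSet",
    "RiskScore",
    "apply_rule",
    "apply_ruleset",
    "correctness_matrix",
    "BinaryRelevanceLearner",
    "RuleBasedClassifier",
    "fit_rule_model",
    "predict_risk_score",
    "predict_class",
    "derive_candidate_rules",
]

_COMPARATORS = {
    "<=": operator.le,
    "<": operator.lt,
    ">=": operator.ge,
    ">": operator.gt,
    "=": operator.eq,
    "==": operator.eq,
}


@dataclass(frozen=True)
class Rule:
    """Single-condition binary rule: ``if feature <cmp> threshold then consequent``."""

    feature: str
    comparator: str
    threshold: float
    consequent: int = 1

    def __post_init__(self) -> None:
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.consequent not in (0, 1):
            raise ValueError("consequent must be 0 or 1")

    def __str__(self) -> str:
        return f"if {self.feature} {self.comparator} {self.threshold:g} then {self.consequent}"


class RuleSet(tuple):
    """Ordered collection of rules, indexable by position."""

    def __new__(cls, rules: Iterable[Rule]):
        rules = tuple(rules)
        if not all(isinstance(r, Rule) for r in rules):
            raise TypeError("RuleSet accepts Rule instances only")
        return super().__new__(cls, rules)

    @classmethod
    def from_json(cls, path: str | Path) -> "RuleSet":
        raw = json.loads(Path(path).read_text())
        return cls(
            Rule(r["feature"], r["comparator"], float(r["threshold"]), int(r.get("consequent", 1)))
            for r in raw
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                [
                    {
                        "feature": r.feature,
                        "comparator": r.comparator,
                        "threshold": r.threshold,
                        "consequent": r.consequent,
                    }
                    for r in self
                ],
                indent=2,
            )
        )


def apply_rule(rule: Rule, patient) -> int:
    """Rule output for one patient: consequent if the condition holds, else 0."""
    if isinstance(patient, pd.Series) or isinstance(patient, dict):
        if rule.feature not in patient:
            raise KeyError(f"patient lacks feature {rule.feature!r}")
        value = patient[rule.feature]
    else:
        raise TypeError("patient must be a mapping or pandas Series")
    return rule.consequent if _COMPARATORS[rule.comparator](value, rule.threshold) else 0


def apply_ruleset(ruleset: Sequence[Rule], X: pd.DataFrame) -> np.ndarray:
    """N x K matrix of rule outputs (vectorized :func:`apply_rule`)."""
    cols = []
    for rule in ruleset:
        if rule.feature not in X.columns:
            raise KeyError(f"cohort lacks feature {rule.feature!r}")
        fires = _COMPARATORS[rule.comparator](X[rule.feature].to_numpy(), rule.threshold)
        cols.append(np.where(fires, rule.consequent, 0))
    return np.column_stack(cols) if cols else np.empty((len(X), 0), dtype=int)


def correctness_matrix(ruleset: Sequence[Rule], cohort: Cohort) -> np.ndarray:
    """N x K binary matrix; entry 1 iff the rule's output equals the true outcome."""
    if len(ruleset) == 0:
        raise ValueError("ruleset is empty")
    T = apply_ruleset(ruleset, cohort.X)
    return (T == cohort.y[:, None]).astype(int)


class BinaryRelevanceLearner(BaseEstimator):
    """Default correctness learner: one probabilistic classifier per rule.

    Each of the K correctness columns gets an independent clone of
    ``base_estimator``; a column with a single class in training (a rule
    that is always correct, or never) falls back to a constant predictor.
    """

    def __init__(self, base_estimator=None, threshold: float = 0.5):
        self.base_estimator = base_estimator
        self.threshold = threshold

    def fit(self, X, R):
        X = np.asarray(X, dtype=float)
        R = np.asarray(R)
        if R.ndim == 1:
            R = R[:, None]
        base = self.base_estimator
        if base is None:
            base = LogisticRegression(max_iter=1000)
        self.estimators_ = []
        self.constants_ = []
        for k in range(R.shape[1]):
            col = R[:, k]
            if len(np.unique(col)) < 2:
                self.estimators_.append(None)
                self.constants_.append(int(col[0]))
            else:
                est = clone(base).fit(X, col)
                self.estimators_.append(est)
                self.constants_.append(None)
        self.n_rules_ = R.shape[1]
        return self

    def predict_proba_matrix(self, X) -> np.ndarray:
        check_is_fitted(self, "estimators_")
        X = np.asarray(X, dtype=float)
        P = np.empty((X.shape[0], self.n_rules_))
        for k, est in enumerate(self.estimators_):
            if est is None:
                P[:, k] = self.constants_[k]
            else:
                P[:, k] = est.predict_proba(X)[:, list(est.classes_).index(1)]
        return P

    def predict(self, X) -> np.ndarray:
        """Predicted correctness r-hat in {0,1}, probabilities cut at ``threshold``."""
        return (self.predict_proba_matrix(X) >= self.threshold).astype(int)


class MemorizingLearner(BaseEstimator):
    """Oracle correctness learner that memorizes training rows exactly.

    Prediction for a row present in training returns its stored correctness
    vector; unseen rows fall back to all-ones (accept every rule).  Used for
    exact equivalence checks against brute-force aggregation.
    """

    def fit(self, X, R):
        self._keys = {tuple(row): np.asarray(r) for row, r in zip(np.asarray(X, float), np.asarray(R))}
        self.n_rules_ = np.asarray(R).shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.ones((X.shape[0], self.n_rules_), dtype=int)
        for i, row in enumerate(X):
            hit = self._keys.get(tuple(row))
            if hit is not None:
                out[i] = hit
        return out


@dataclass(frozen=True)
class RiskScore:
    """Aggregated mortality score for one patient.

    ``value`` is the fraction of accepted rules predicting death, ``q`` the
    number of accepted rules; ``fallback`` flags the Q=0 case (score 0,
    survival by convention).
    """

    value: float
    q: int
    fallback: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("risk score must lie in [0,1]")
        if self.q < 0:
            raise ValueError("accepted-rule count must be nonnegative")


def predict_class(score: RiskScore | float) -> int:
    """Final label: 1 (death) iff the mortality score is >= 0.5 (inclusive)."""
    value = score.value if isinstance(score, RiskScore) else float(score)
    return int(value >= 0.5)


class RuleBasedClassifier(ClassifierMixin, BaseEstimator):
    """Rule set + correctness learner + score aggregation as one estimator.

    Parameters
    ----------
    rules : sequence of Rule
        The clinical rule set (K >= 1).
    learner : estimator, optional
        Correctness learner implementing ``fit(X, R)`` and
        ``predict(X) -> N x K`` binary matrix.  Defaults to
        :class:`BinaryRelevanceLearner`.
    min_quality, max_rules :
        When ``rules`` is None, candidate rules are derived from the
        training data by :func:`derive_candidate_rules` with this balanced-
        accuracy floor, keeping at most ``max_rules`` of the best.
    """

    def __init__(
        self,
        rules: Sequence[Rule] | None = None,
        learner=None,
        min_quality: float = 0.6,
        max_rules: int = 10,
    ):
        self.rules = rules
        self.learner = learner
        self.min_quality = min_quality
        self.max_rules = max_rules

    def _check_inputs(self, X):
        if isinstance(X, Cohort):
            return X.X
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=list(self.feature_names_in_))

    def fit(self, X, y=None):
        if isinstance(X, Cohort):
            cohort = X
        else:
            if y is None:
                raise ValueError("y required when X is not a Cohort")
            Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
            if not isinstance(X, pd.DataFrame):
                Xdf.columns = [str(c) for c in Xdf.columns]
            cohort = Cohort(Xdf, np.asarray(y))
        if len(np.unique(cohort.y)) < 2:
            raise ValueError("training cohort must contain both outcomes")
        if self.rules is None:
            rules = list(derive_candidate_rules(cohort, min_quality=self.min_quality))
            rules = rules[: self.max_rules]
        else:
            rules = list(self.rules)
        if len(rules) == 0:
            raise ValueError("RuleBasedClassifier requires a nonempty rule set")
        R = correctness_matrix(rules, cohort)
        learner = self.learner if self.learner is not None else BinaryRelevanceLearner()
        self.learner_ = clone(learner).fit(cohort.values(), R)
        self.ruleset_ = RuleSet(rules)
        self.feature_names_in_ = np.asarray(cohort.feature_names)
        self.n_features_in_ = len(cohort.feature_names)
        self.classes_ = np.array([0, 1])
        return self

    def risk_scores(self, X) -> list[RiskScore]:
        """Per-patient :class:`RiskScore` (value, accepted-rule count, fallback flag)."""
        check_is_fitted(self, "learner_")
        Xdf = self._check_inputs(X)
        T = apply_ruleset(self.ruleset_, Xdf)  # rule outputs t_ij
        Rhat = self.learner_.predict(Xdf.to_numpy(dtype=float))
        scores = []
        for i in range(len(Xdf)):
            q = int(Rhat[i].sum())
            if q == 0:
                scores.append(RiskScore(0.0, 0, fallback=True))
            else:
                deaths = int((Rhat[i] * T[i]).sum())
                scores.append(RiskScore(deaths / q, q))
        return scores

    def decision_function(self, X) -> np.ndarray:
        return np.array([s.value for s in self.risk_scores(X)])

    def predict(self, X) -> np.ndarray:
        return np.array([predict_class(s) for s in self.risk_scores(X)])


def fit_rule_model(
    ruleset: Sequence[Rule], cohort: Cohort, learner=None
) -> RuleBasedClassifier:
    """Convenience wrapper: fit a :class:`RuleBasedClassifier` on a cohort."""
    return RuleBasedClassifier(rules=list(ruleset), learner=learner).fit(cohort)


def predict_risk_score(model: RuleBasedClassifier, patient) -> RiskScore:
    """Aggregated mortality score for a single patient (mapping or Series)."""
    if isinstance(patient, dict):
        patient = pd.Series(patient)
    X = patient.to_frame().T[list(model.feature_names_in_)]
    return model.risk_scores(X)[0]


def derive_candidate_rules(
    cohort: Cohort,
    features: Sequence[str] | None = None,
    grid: dict[str, Sequence[float]] | None = None,
    min_quality: float = 0.6,
    comparators: Sequence[str] = ("<=", ">="),
) -> RuleSet:
    """Threshold-sweep generator of candidate single-condition rules.

    For every feature, comparator and grid threshold, the rule
    ``feature <cmp> threshold -> death`` is scored by training balanced
    accuracy ((SE+SP)/2) of its predictions against the true outcomes;
    rules at or above ``min_quality`` are kept, sorted by quality
    (descending, ties broken deterministically by feature/comparator/
    threshold).  This replaces a clinician-validated rule-derivation
    workflow with a reproducible data-driven sweep.
    """
    if features is None:
        features = [s.name for s in cohort.schema if s.kind in ("numeric", "ordinal")]
    scored = []
    for feat in features:
        values = cohort.X[feat].to_numpy(dtype=float)
        thresholds = (
            grid.get(feat) if grid and feat in grid else np.unique(np.quantile(values, np.linspace(0.05, 0.95, 19)))
        )
        for cmp in comparators:
            for thr in thresholds:
                rule = Rule(feat, cmp, float(thr), 1)
                pred = np.where(_COMPARATORS[cmp](values, thr), 1, 0)
                if len(np.unique(cohort.y)) < 2:
                    raise ValueError("cohort must contain both outcomes")
                quality = balanced_accuracy_score(cohort.y, pred)
                if quality >= min_quality:
                    scored.append((quality, rule))
    scored.sort(key=lambda t: (-t[0], t[1].feature, t[1].comparator, t[1].threshold))
    return RuleSet(r for _, r in scored)
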