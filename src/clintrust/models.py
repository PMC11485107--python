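"""Uniform trainable-model harness over the five compared risk models.

Every model — the predefined GRACE score and the four learned white-box
models (logistic regression, Naive Bayes, shallow decision tree,
rule-based) — is exposed through the same scikit-learn contract
(``fit(X, y)`` / ``predict`` / a real-valued score), so the trust and
performance modules treat them identically.

Learner internals are delegated to scikit-learn; this module only enforces
the preprocessing and hyperparameters that define each configuration:

* logistic — z-scoring then L2 logistic regression;
* naive_bayes — clinical discretization (sex-specific creatinine bins,
  quantile bins for untabled numerics) then a categorical NB;
* decision_tree — CART limited to depth 3 to preserve interpretability;
* rule_based — :class:`~clintrust.rules.RuleBasedClassifier`;
* grace — no training; dataset columns are aliased onto the eight GRACE
  variables (STEMI stands in for ST-segment deviation, a troponin cut for
  elevated cardiac markers) and the tabulated points are summed.

The learned models default to balanced class weighting / priors because
the mortality outcome is rare (~10%): without it the majority class
dominates and sensitivity collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.naive_bayes import CategoricalNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

from .cohort import CLINICAL_DISCRETIZATION, DiscretizationTable
from .grace import GraceClassifier, VARIABLES as GRACE_VARIABLES
from .rules import Rule, RuleBasedClassifier

__all__ = [
    "MODEL_KINDS",
    "ModelSpec",
    "ClinicalDiscretizer",
    "GraceCohortAdapter",
    "build_model",
    "conditional_probability_table",
]

MODEL_KINDS = ("grace", "logistic", "naive_bayes", "decision_tree", "rule_based")

#: Default dataset-column -> GRACE-variable aliases.
DEFAULT_GRACE_ALIASES = {"stemi": "st_deviation", "troponin": "elevated_markers"}


class ClinicalDiscretizer(TransformerMixin, BaseEstimator):
    """Map every feature to a small non-negative integer code.

    Variables present in ``table`` get their clinical bins (minus 1, to be
    0-based); binary 0/1 features pass through; integer-valued features
    with few levels (e.g. Killip 1-4) are offset to 0; remaining numerics
    are quantile-binned with edges learned in ``fit``.  Sex-specific bins
    use a ``sex`` column if present (dropped from the output), else
    ``default_sex``.
    """

    def __init__(
        self,
        table: DiscretizationTable = CLINICAL_DISCRETIZATION,
        n_quantile_bins: int = 4,
        max_int_levels: int = 6,
        default_sex: str = "M",
    ):
        self.table = table
        self.n_quantile_bins = n_quantile_bins
        self.max_int_levels = max_int_levels
        self.default_sex = default_sex

    def fit(self, X: pd.DataFrame, y=None):
        X = self._as_frame(X)
        self.strategy_ = {}
        self.edges_ = {}
        self.offset_ = {}
        self.n_categories_ = {}
        for col in X.columns:
            if col == "sex":
                continue
            v = X[col].to_numpy()
            if col in self.table.bins:
                self.strategy_[col] = "table"
                entry = self.table.bins[col]
                groups = entry.values() if isinstance(entry, dict) else [entry]
                self.n_categories_[col] = max(len(g) for g in groups)
            elif np.isin(v, [0, 1]).all():
                self.strategy_[col] = "binary"
                self.n_categories_[col] = 2
            elif np.allclose(v, np.round(v)) and len(np.unique(v)) <= self.max_int_levels:
                self.strategy_[col] = "int"
                self.offset_[col] = int(np.min(v))
                self.n_categories_[col] = int(np.max(v)) - int(np.min(v)) + 1
            else:
                self.strategy_[col] = "quantile"
                qs = np.linspace(0, 1, self.n_quantile_bins + 1)[1:-1]
                self.edges_[col] = np.unique(np.quantile(v.astype(float), qs))
                self.n_categories_[col] = len(self.edges_[col]) + 1
        self.feature_names_out_ = [c for c in X.columns if c != "sex"]
        return self

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("ClinicalDiscretizer requires a DataFrame with named columns")
        return X

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "strategy_")
        X = self._as_frame(X)
        sex = X["sex"].to_numpy() if "sex" in X.columns else np.full(len(X), self.default_sex)
        out = {}
        for col, strat in self.strategy_.items():
            v = X[col].to_numpy()
            if strat == "table":
                codes = self.table.categorize(col, v, sex) - 1
            elif strat == "binary":
                codes = v.astype(int)
            elif strat == "int":
                codes = np.round(v).astype(int) - self.offset_[col]
            else:
                codes = np.digitize(v.astype(float), self.edges_[col], right=False)
            out[col] = np.clip(codes, 0, self.n_categories_[col] - 1)
        return pd.DataFrame(out, index=X.index)[self.feature_names_out_]


class GraceCohortAdapter(ClassifierMixin, BaseEstimator):
    """Apply the GRACE score to a study cohort whose columns differ from
    the eight canonical GRACE variables.

    ``aliases`` renames dataset columns onto GRACE variables (default:
    STEMI -> ST-segment deviation, troponin -> elevated cardiac markers).
    A continuous column aliased onto a binary GRACE variable is binarized
    at ``marker_threshold``.  Missing binary variables are filled with 0.
    ``fit`` validates configuration only — the score is predefined.
    """

    def __init__(
        self,
        threshold: int | None = None,
        aliases: dict[str, str] | None = None,
        marker_threshold: float = 0.1,
        creatinine_umol: bool = True,
    ):
        self.threshold = threshold
        self.aliases = aliases
        self.marker_threshold = marker_threshold
        self.creatinine_umol = creatinine_umol

    def _grace_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        aliases = DEFAULT_GRACE_ALIASES if self.aliases is None else self.aliases
        df = X.rename(columns=aliases).copy()
        for var in ("elevated_markers", "cardiac_arrest", "st_deviation"):
            if var not in df.columns:
                df[var] = 0
            elif not np.isin(df[var].to_numpy(), [0, 1]).all():
                df[var] = (df[var].to_numpy(dtype=float) >= self.marker_threshold).astype(int)
        missing = set(GRACE_VARIABLES) - set(df.columns)
        if missing:
            raise ValueError(f"cannot map cohort onto GRACE variables, missing {sorted(missing)}")
        df["killip"] = df["killip"].round().astype(int)
        return df[list(GRACE_VARIABLES)]

    def fit(self, X=None, y=None):
        self._grace_ = GraceClassifier(self.threshold, self.creatinine_umol).fit()
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns)
            self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "_grace_")
        return self._grace_.decision_function(self._grace_frame(X))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "_grace_")
        return self._grace_.predict(self._grace_frame(X))


@dataclass
class ModelSpec:
    """Configuration for one harness model.

    ``params`` are passed to the underlying constructor (after the
    paper-fixed defaults); ``grid`` activates a grid search over the given
    parameter grid with balanced accuracy as the selection score.
    """

    kind: str
    params: dict = dc_field(default_factory=dict)
    grid: dict | None = None
    rules: Sequence[Rule] | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")


def build_model(spec: ModelSpec):
    """Instantiate a contract-conforming estimator from a spec."""
    p = dict(spec.params)
    if spec.kind == "grace":
        if p.get("threshold") is None:
            raise ValueError("grace model requires an explicit 'threshold' parameter")
        model = GraceCohortAdapter(**p)
    elif spec.kind == "logistic":
        p.setdefault("class_weight", "balanced")
        p.setdefault("max_iter", 1000)
        model = Pipeline(
            [("scale", StandardScaler()), ("clf", LogisticRegression(**p))]
        )
    elif spec.kind == "naive_bayes":
        disc = {k: p.pop(k) for k in ("n_quantile_bins", "default_sex") if k in p}
        p.setdefault("alpha", 1.0)
        p.setdefault("class_prior", [0.5, 0.5])
        model = Pipeline(
            [("disc", ClinicalDiscretizer(**disc)), ("clf", CategoricalNB(**p))]
        )
    elif spec.kind == "decision_tree":
        p.setdefault("max_depth", 3)
        p.setdefault("class_weight", "balanced")
        p.setdefault("random_state", 0)
        model = DecisionTreeClassifier(**p)
    else:  # rule_based
        model = RuleBasedClassifier(rules=spec.rules, **p)
    if spec.grid:
        prefix = "clf__" if isinstance(model, Pipeline) else ""
        grid = {prefix + k if "__" not in k else k: v for k, v in spec.grid.items()}
        model = GridSearchCV(model, grid, scoring="balanced_accuracy", cv=3)
    return model


def conditional_probability_table(model) -> dict[str, pd.DataFrame]:
    """Per-feature conditional category probabilities of a fitted NB model.

    Returns ``{feature: DataFrame}`` with one row per class (index 0
    survival, 1 death) and one column per 1-based category; each row sums
    to 1 (under the configured smoothing).
    """
    if isinstance(model, GridSearchCV):
        model = model.best_estimator_
    if not (isinstance(model, Pipeline) and isinstance(model[-1], CategoricalNB)):
        raise TypeError("expected a fitted naive_bayes harness model")
    nb: CategoricalNB = model[-1]
    check_is_fitted(nb, "feature_log_prob_")
    names = model[0].feature_names_out_
    out = {}
    for name, logp in zip(names, nb.feature_log_prob_):
        probs = np.exp(logp)
        out[name] = pd.DataFrame(
            probs, index=nb.classes_, columns=range(1, probs.shape[1] + 1)
        )
    return out
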