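"""GRACE risk-score calculator for acute coronary syndrome patients.

The GRACE (Global Registry of Acute Coronary Events) score estimates
6-month mortality risk after hospital admission with an ACS diagnosis.
Eight admission variables each contribute a tabulated number of points;
the total ranges from 2 to 383.  The score is fully predefined — there is
no training phase — which makes it the natural clinical reference against
which learned risk models are compared.

Bin-edge convention: printed ranges such as "70-89" / "90-109" are
implemented as lower-inclusive half-open intervals ([70, 90), [90, 110),
...), so the bins partition the positive axis; "<70" means (0, 70) and
">200" means [200, inf).  Creatinine is in mg/dl here — cohorts storing
umol/L convert via :func:`umol_to_mgdl` (divide by 88.4).

Binary high-risk classification requires an explicit score threshold; the
dichotomization cut-off is configuration, never defaulted, and the
comparison is strict (total > threshold -> high risk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GRACE_MIN",
    "GRACE_MAX",
    "GraceInput",
    "GraceScore",
    "grace_points",
    "grace_total",
    "grace_classify",
    "umol_to_mgdl",
    "GraceClassifier",
]

GRACE_MIN = 2
GRACE_MAX = 383

# (lower edge, points) per variable; a value lands in the last bin whose
# lower edge does not exceed it.  Lower edges are the printed lower bounds.
_POINTS: dict[str, list[tuple[float, int]]] = {
    "age": [(0, 0), (40, 18), (50, 36), (60, 55), (70, 73), (80, 91)],
    "creatinine": [(0, 2), (0.4, 5), (0.8, 8), (1.2, 11), (1.6, 14), (2, 23), (4, 31)],
    "heart_rate": [(0, 0), (70, 7), (90, 13), (110, 23), (150, 36), (200, 46)],
    "killip": [(1, 0), (2, 21), (3, 43), (4, 64)],
    "sbp": [(0, 63), (80, 58), (100, 47), (120, 37), (140, 26), (160, 11), (200, 0)],
    "elevated_markers": [(0, 0), (1, 15)],
    "cardiac_arrest": [(0, 0), (1, 43)],
    "st_deviation": [(0, 0), (1, 30)],
}

VARIABLES = tuple(_POINTS)


@dataclass(frozen=True)
class GraceInput:
    """The eight GRACE admission variables for one patient.

    age in years, creatinine in mg/dl, heart_rate in bpm, killip grade in
    {1,2,3,4}, sbp in mmHg; the last three are 0/1 indicators.
    """

    age: float
    creatinine: float
    heart_rate: float
    killip: int
    sbp: float
    elevated_markers: int
    cardiac_arrest: int
    st_deviation: int

    def __post_init__(self) -> None:
        for name in ("age", "creatinine", "heart_rate", "sbp"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.killip not in (1, 2, 3, 4):
            raise ValueError(f"killip grade must be 1..4, got {self.killip}")
        for name in ("elevated_markers", "cardiac_arrest", "st_deviation"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass(frozen=True)
class GraceScore:
    """Per-variable points plus their total, kept for audit."""

    points: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total != sum(self.points.values()):
            raise ValueError("total does not equal the sum of per-variable points")
        if not GRACE_MIN <= self.total <= GRACE_MAX:
            raise ValueError(f"total {self.total} outside [{GRACE_MIN}, {GRACE_MAX}]")


def grace_points(variable: str, value: float) -> int:
    """Points contributed by one variable at the given raw value."""
    if variable not in _POINTS:
        raise KeyError(f"unknown GRACE variable {variable!r}")
    if not np.isfinite(value):
        raise ValueError(f"{variable}: non-finite value {value}")
    table = _POINTS[variable]
    if value < table[0][0]:
        raise ValueError(f"{variable}: value {value} below valid range")
    pts = table[0][1]
    for lo, p in table:
        if value >= lo:
            pts = p
    return pts


def grace_total(inp: GraceInput) -> GraceScore:
    """Sum the eight per-variable point contributions."""
    pts = {v: grace_points(v, getattr(inp, v)) for v in VARIABLES}
    return GraceScore(pts, sum(pts.values()))


def grace_classify(score: GraceScore | int, threshold: int) -> int:
    """Binary risk label: 1 (high risk) iff total strictly exceeds threshold."""
    if not GRACE_MIN <= threshold <= GRACE_MAX:
        raise ValueError(f"threshold must lie in [{GRACE_MIN}, {GRACE_MAX}]")
    total = score.total if isinstance(score, GraceScore) else int(score)
    return int(total > threshold)


def umol_to_mgdl(creatinine_umol: float) -> float:
    """Convert creatinine from umol/L to mg/dl (divide by 88.4)."""
    c = np.asarray(creatinine_umol, dtype=float)
    if not (c > 0).all():
        raise ValueError("creatinine must be positive")
    out = c / 88.4
    return float(out) if out.ndim == 0 else out


class GraceClassifier(ClassifierMixin, BaseEstimator):
    """Predefined GRACE score as a scikit-learn classifier.

    ``fit`` only validates the configuration (the score has no training
    phase); ``decision_function`` returns the integer total and ``predict``
    the strict-threshold high-risk label.

    Parameters
    ----------
    threshold : int
        Required high-risk cut-off on the total score (no default: the
        dichotomization point is a clinical configuration choice).
    creatinine_umol : bool, default True
        If True, the ``creatinine`` column is in umol/L and is converted to
        mg/dl internally.
    """

    def __init__(self, threshold: int | None = None, creatinine_umol: bool = True):
        self.threshold = threshold
        self.creatinine_umol = creatinine_umol

    def fit(self, X=None, y=None):
        if self.threshold is None:
            raise ValueError("GraceClassifier requires an explicit threshold")
        if not GRACE_MIN <= self.threshold <= GRACE_MAX:
            raise ValueError(f"threshold must lie in [{GRACE_MIN}, {GRACE_MAX}]")
        self.classes_ = np.array([0, 1])
        if X is not None:
            self.feature_names_in_ = np.asarray(self._frame(X).columns)
        self.n_features_in_ = 8
        return self

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = set(VARIABLES) - set(X.columns)
            if missing:
                raise ValueError(f"missing GRACE variables: {sorted(missing)}")
            return X[list(VARIABLES)]
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 8:
            raise ValueError("array input must be N x 8 in GRACE variable order")
        return pd.DataFrame(X, columns=list(VARIABLES))

    def score_table(self, X) -> pd.DataFrame:
        """Per-patient per-variable points plus the total, for audit."""
        check_is_fitted(self, "classes_")
        df = self._frame(X).copy()
        if self.creatinine_umol:
            df["creatinine"] = umol_to_mgdl(df["creatinine"].to_numpy())
        out = {}
        for var in VARIABLES:
            out[var] = [grace_points(var, v) for v in df[var].to_numpy(dtype=float)]
        table = pd.DataFrame(out, index=df.index)
        table["total"] = table.sum(axis=1)
        return table

    def decision_function(self, X) -> np.ndarray:
        return self.score_table(X)["total"].to_numpy()

    def predict(self, X) -> np.ndarray:
        totals = self.decision_function(X)
        return (totals > self.threshold).astype(int)
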