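"""Performance metrics and repeated-holdout comparison harness.

The outcome is rare (about 10% mortality), so accuracy is uninformative;
performance is summarized by sensitivity SE = TP/(TP+FN), specificity
SP = TN/(TN+FP) and their geometric mean G_mean = sqrt(SE * SP), which is
high only when both are.  The positive label is death (1) throughout.

Models are compared over repeated stratified holdout runs (default 10)
and per-pair Mann-Whitney U tests on the run-level G_mean values.  The
test dialect is the two-sided normal approximation *with* continuity
correction (and tie correction), the convention whose p-values match
standard statistical software on 10-vs-10 comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.model_selection import train_test_split

from .cohort import Cohort

__all__ = [
    "ConfusionCounts",
    "PerfMetrics",
    "RunSeries",
    "ComparisonResult",
    "confusion_counts",
    "sens_spec_gmean",
    "repeated_holdout",
    "mann_whitney",
    "compare_methods",
    "five_number_summary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerfMetrics:
    """SE, SP and G_mean as fractions in [0, 1]."""

    se: float
    sp: float
    gmean: float

    def __post_init__(self) -> None:
        if abs(self.gmean - np.sqrt(self.se * self.sp)) > 1e-12:
            raise ValueError("gmean must equal sqrt(se * sp)")


def confusion_counts(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    """2x2 cross-tabulation with 1 = positive (death)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    for name, v in (("y_true", y_true), ("y_pred", y_pred)):
        if not np.isin(v, [0, 1]).all():
            raise ValueError(f"{name} contains non-binary values")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def sens_spec_gmean(counts: ConfusionCounts) -> PerfMetrics:
    if counts.tp + counts.fn == 0:
        raise ValueError("no positive (death) instances: sensitivity undefined")
    if counts.tn + counts.fp == 0:
        raise ValueError("no negative (survival) instances: specificity undefined")
    se = counts.tp / (counts.tp + counts.fn)
    sp = counts.tn / (counts.tn + counts.fp)
    return PerfMetrics(se, sp, float(np.sqrt(se * sp)))


@dataclass
class RunSeries:
    """Per-run train/test metrics for one model over repeated holdouts."""

    train: list[PerfMetrics]
    test: list[PerfMetrics]
    seeds: list[int]
    n_runs_flag_degenerate: bool = False

    @property
    def n_runs(self) -> int:
        return len(self.test)

    def metric(self, name: str, split: str = "test") -> np.ndarray:
        runs = getattr(self, split)
        if name not in ("se", "sp", "gmean"):
            raise KeyError(f"unknown metric {name!r}")
        return np.array([getattr(m, name) for m in runs])

    def summary(self, split: str = "test") -> dict[str, tuple[float, float]]:
        """Mean +/- std (ddof=0; 0 with flag when n_runs == 1) per metric."""
        out = {}
        for name in ("gmean", "se", "sp"):
            vals = self.metric(name, split)
            std = float(vals.std(ddof=0)) if len(vals) > 1 else 0.0
            out[name] = (float(vals.mean()), std)
        return out


def repeated_holdout(
    model_factory: Callable[[], object],
    cohort: Cohort,
    n_runs: int = 10,
    test_fraction: float = 0.3,
    base_seed: int = 0,
) -> RunSeries:
    """Fit/evaluate over ``n_runs`` stratified splits seeded base_seed..+n_runs-1.

    ``model_factory`` returns a fresh unfitted estimator per run (a fitted
    sklearn estimator works too — it is cloned).  A split that loses a
    class is redrawn with an incremented seed.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(np.unique(cohort.y)) < 2:
        raise ValueError("cohort must contain both outcomes")
    train_ms, test_ms, seeds = [], [], []
    for run in range(n_runs):
        seed = base_seed + run
        for attempt in range(100):
            idx_tr, idx_te = train_test_split(
                np.arange(cohort.n),
                test_size=test_fraction,
                random_state=seed + 7919 * attempt,
                stratify=cohort.y,
            )
            if len(set(cohort.y[idx_tr])) == 2 and len(set(cohort.y[idx_te])) == 2:
                break
        else:  # pragma: no cover
            raise ValueError("could not draw a split containing both classes")
        sub_tr = Cohort(cohort.X.iloc[idx_tr].reset_index(drop=True), cohort.y[idx_tr],
                        cohort.schema, None if cohort.sex is None else cohort.sex[idx_tr])
        model = model_factory() if callable(model_factory) else clone(model_factory)
        model.fit(sub_tr.X, sub_tr.y)
        for idx, store in ((idx_tr, train_ms), (idx_te, test_ms)):
            pred = np.asarray(model.predict(cohort.X.iloc[idx]))
            store.append(sens_spec_gmean(confusion_counts(cohort.y[idx], pred)))
        seeds.append(seed)
    return RunSeries(train_ms, test_ms, seeds, n_runs_flag_degenerate=n_runs == 1)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with continuity and tie correction.

    Returns (U for sample a, p).  U(a, b) + U(b, a) = n1 * n2 in the
    absence of ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def five_number_summary(values: Sequence[float]) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return {"min": float(v.min()), "q1": float(q1), "median": float(med),
            "q3": float(q3), "max": float(v.max())}


@dataclass
class ComparisonResult:
    """All pairwise U tests plus per-method boxplot summaries."""

    pairs: list[dict] = field(default_factory=list)
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)


def compare_methods(
    series: dict[str, RunSeries], metric: str = "gmean", split: str = "test"
) -> ComparisonResult:
    """Pairwise Mann-Whitney comparison of run-level metrics across methods."""
    if len(series) < 2:
        raise ValueError("need at least two methods to compare")
    lengths = {s.n_runs for s in series.values()}
    if len(lengths) != 1:
        raise ValueError("all methods must have the same number of runs")
    values = {name: s.metric(metric, split) for name, s in series.items()}
    result = ComparisonResult()
    names = list(values)
    for i, m1 in enumerate(names):
        for m2 in names[i + 1:]:
            u, p = mann_whitney(values[m1], values[m2])
            result.pairs.append({"method_1": m1, "method_2": m2,
                                 "U": u, "p_value": p})
    result.summaries = {name: five_number_summary(v) for name, v in values.items()}
    return result
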