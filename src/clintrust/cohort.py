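"""Patient-cohort container, CSV I/O, z-score normalization and clinical discretization.

A cohort is a plain table: one row per patient, numeric / binary risk
factors, a binary ``outcome`` column (0 survival, 1 death) and an optional
``sex`` column (``M``/``F``).  The container wraps a :class:`pandas.DataFrame`
so downstream code can use ordinary pandas/numpy operations.

Z-scoring uses the population standard deviation (``ddof=0``) throughout;
the same convention scikit-learn's ``StandardScaler`` uses.

The default discretization table maps each numeric risk factor to a small
ordered set of clinically meaningful categories (1-based); creatinine bins
are sex-specific.  Bins are lower-inclusive half-open intervals with
open-ended edges, so discretization is total on the real line and monotone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureSpec",
    "Cohort",
    "NormalizationParams",
    "Bin",
    "DiscretizationTable",
    "CLINICAL_DISCRETIZATION",
    "read_cohort",
    "write_cohort",
    "zscore_normalize",
    "inverse_normalize",
    "discretize_clinical",
]

FeatureKind = Literal["numeric", "binary", "ordinal"]


class CohortError(ValueError):
    """Raised on malformed cohort data or schema violations."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of one risk factor.

    Parameters
    ----------
    name : str
        Column name; unique within a schema.
    kind : {"numeric", "binary", "ordinal"}
    units : str
        Free text, e.g. ``"years"``, ``"mmHg"``, ``"umol/L"``.
    sex_specific : bool
        True if the feature's clinical bins differ by sex (creatinine).
    categories : tuple of int, optional
        Ordered category indices, required for ordinal features.
    """

    name: str
    kind: FeatureKind = "numeric"
    units: str = ""
    sex_specific: bool = False
    categories: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("numeric", "binary", "ordinal"):
            raise CohortError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.kind == "ordinal" and not self.categories:
            raise CohortError(f"ordinal feature {self.name!r} needs a category list")


@dataclass
class Cohort:
    """N patients x M features with a binary outcome.

    Attributes
    ----------
    X : pandas.DataFrame
        Feature matrix, one column per schema entry.
    y : numpy.ndarray
        Outcome labels in {0, 1}; 1 = death.
    schema : list of FeatureSpec
    sex : numpy.ndarray or None
        Optional per-patient ``"M"``/``"F"`` vector.
    """

    X: pd.DataFrame
    y: np.ndarray
    schema: list[FeatureSpec] = field(default_factory=list)
    sex: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if not self.schema:
            self.schema = [FeatureSpec(c) for c in self.X.columns]
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise CohortError("duplicate feature names in schema")
        if list(self.X.columns) != names:
            raise CohortError(f"columns {list(self.X.columns)} do not match schema {names}")
        if len(self.X) < 1:
            raise CohortError("cohort must contain at least one patient")
        if len(self.y) != len(self.X):
            raise CohortError("outcome length does not match number of rows")
        if not np.isin(self.y, [0, 1]).all():
            bad = sorted(set(np.unique(self.y)) - {0, 1})
            raise CohortError(f"outcome must be 0/1, found {bad}")
        if self.X.isna().any().any():
            raise CohortError("cohort contains missing values")
        for s in self.schema:
            if s.kind == "binary":
                col = self.X[s.name].to_numpy()
                if not np.isin(col, [0, 1]).all():
                    raise CohortError(f"binary feature {s.name!r} has values outside {{0,1}}")
        if self.sex is not None:
            self.sex = np.asarray(self.sex)
            if len(self.sex) != len(self.X):
                raise CohortError("sex vector length does not match number of rows")
            if not np.isin(self.sex, ["M", "F"]).all():
                raise CohortError("sex values must be 'M' or 'F'")

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def spec(self, name: str) -> FeatureSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise CohortError(f"unknown feature {name!r}")


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature mean/std recorded by :func:`zscore_normalize`."""

    mean: dict[str, float]
    std: dict[str, float]

    def __post_init__(self) -> None:
        for name, s in self.std.items():
            if not s > 0:
                raise CohortError(f"non-positive std for feature {name!r}")


def read_cohort(
    path: str | Path,
    schema: Sequence[FeatureSpec] | None = None,
    missing_policy: Literal["fail", "drop_row"] = "fail",
) -> Cohort:
    """Load a cohort CSV (header row, ``outcome`` column, optional ``sex``).

    With ``missing_policy="drop_row"`` rows containing any missing value are
    dropped (count available via logging); with ``"fail"`` (default) any
    missing value raises :class:`CohortError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - message passthrough
        raise CohortError(f"malformed CSV {path}: {exc}") from exc
    if "outcome" not in df.columns:
        raise CohortError(f"{path}: no 'outcome' column")
    sex = None
    if "sex" in df.columns:
        sex_series = df.pop("sex")
    else:
        sex_series = None
    y = df.pop("outcome")
    if schema is not None:
        names = [s.name for s in schema]
        unknown = set(names) - set(df.columns)
        if unknown:
            raise CohortError(f"{path}: schema features missing from file: {sorted(unknown)}")
        df = df[names]
        schema = list(schema)
    if df.isna().any().any() or y.isna().any():
        if missing_policy == "fail":
            raise CohortError(f"{path}: missing values present under policy='fail'")
        keep = ~(df.isna().any(axis=1) | y.isna())
        df, y = df[keep], y[keep]
        if sex_series is not None:
            sex_series = sex_series[keep]
    if sex_series is not None:
        sex = sex_series.to_numpy()
    return Cohort(df.reset_index(drop=True), y.to_numpy(), schema or [], sex)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to CSV, inverse of :func:`read_cohort`."""
    df = cohort.X.copy()
    df["outcome"] = cohort.y
    if cohort.sex is not None:
        df["sex"] = cohort.sex
    df.to_csv(path, index=False)


def zscore_normalize(
    cohort: Cohort, features: Sequence[str] | None = None
) -> tuple[Cohort, NormalizationParams]:
    """Z-score the selected numeric features (population std, ddof=0).

    Returns the normalized cohort and the parameters needed to invert the
    transform.  Constant (zero-variance) features raise an error naming the
    feature.
    """
    if features is None:
        features = [s.name for s in cohort.schema if s.kind == "numeric"]
    X = cohort.X.copy()
    mean, std = {}, {}
    for name in features:
        spec = cohort.spec(name)
        if spec.kind != "numeric":
            raise CohortError(f"feature {name!r} is {spec.kind}, not numeric")
        col = X[name].to_numpy(dtype=float)
        m, s = float(col.mean()), float(col.std(ddof=0))
        if s == 0.0:
            raise CohortError(f"feature {name!r} has zero variance")
        X[name] = (col - m) / s
        mean[name], std[name] = m, s
    out = replace(cohort, X=X)
    return out, NormalizationParams(mean, std)


def inverse_normalize(cohort: Cohort, params: NormalizationParams) -> Cohort:
    """Undo :func:`zscore_normalize`."""
    X = cohort.X.copy()
    for name, m in params.mean.items():
        X[name] = X[name].to_numpy(dtype=float) * params.std[name] + m
    return replace(cohort, X=X)


@dataclass(frozen=True)
class Bin:
    """Half-open interval [lo, hi) mapped to a 1-based category index."""

    lo: float
    hi: float
    category: int


@dataclass(frozen=True)
class DiscretizationTable:
    """Ordered, exhaustive bins per variable; creatinine-style entries may be
    keyed by sex (``{"M": [...], "F": [...]}``)."""

    bins: dict[str, list[Bin] | dict[str, list[Bin]]]

    def __post_init__(self) -> None:
        for var, entry in self.bins.items():
            groups = entry.values() if isinstance(entry, dict) else [entry]
            for bins in groups:
                cats = [b.category for b in bins]
                if cats != list(range(1, len(bins) + 1)):
                    raise CohortError(f"{var}: categories must be consecutive from 1, got {cats}")
                if bins[0].lo != -np.inf or bins[-1].hi != np.inf:
                    raise CohortError(f"{var}: edge bins must be open-ended")
                for a, b in zip(bins, bins[1:]):
                    if a.hi != b.lo:
                        raise CohortError(f"{var}: bins must tile the line, gap at {a.hi}")

    def variables(self) -> list[str]:
        return list(self.bins)

    def is_sex_specific(self, var: str) -> bool:
        return isinstance(self.bins[var], dict)

    def categorize(self, var: str, values: np.ndarray, sex: np.ndarray | None = None) -> np.ndarray:
        entry = self.bins[var]
        values = np.asarray(values, dtype=float)
        if not np.isfinite(values).all():
            raise CohortError(f"{var}: non-finite values cannot be discretized")
        if isinstance(entry, dict):
            if sex is None:
                raise CohortError(f"{var}: sex-specific bins but no sex vector given")
            out = np.empty(len(values), dtype=int)
            for s, bins in entry.items():
                mask = sex == s
                out[mask] = _digitize(values[mask], bins)
            return out
        return _digitize(values, entry)

    @classmethod
    def from_json(cls, path: str | Path) -> "DiscretizationTable":
        """Load from JSON: {variable: [{lo, hi, category}] | {M: [...], F: [...]}}."""
        raw = json.loads(Path(path).read_text())
        def mk(lst):
            return [
                Bin(
                    -np.inf if b["lo"] is None else float(b["lo"]),
                    np.inf if b["hi"] is None else float(b["hi"]),
                    int(b["category"]),
                )
                for b in lst
            ]
        bins: dict = {}
        for var, entry in raw.items():
            bins[var] = {s: mk(v) for s, v in entry.items()} if isinstance(entry, dict) else mk(entry)
        return cls(bins)


def _digitize(values: np.ndarray, bins: list[Bin]) -> np.ndarray:
    edges = [b.lo for b in bins[1:]]  # interior lower edges
    return np.digitize(values, edges, right=False) + 1


def _tile(edges: Sequence[float]) -> list[Bin]:
    """Build consecutive half-open bins from interior edges."""
    lo = [-np.inf, *edges]
    hi = [*edges, np.inf]
    return [Bin(a, b, i + 1) for i, (a, b) in enumerate(zip(lo, hi))]


#: Clinically motivated categories for the numeric ACS risk factors.
#: All intervals are lower-inclusive: a value equal to an edge falls in the
#: higher category (age exactly 40 -> category 2).  Creatinine is in umol/L
#: with sex-specific edges.
CLINICAL_DISCRETIZATION = DiscretizationTable(
    {
        "age": _tile([40, 50, 60, 70, 80]),
        "sbp": _tile([120, 130, 140, 180]),
        "heart_rate": _tile([60, 100]),
        "creatinine": {
            "M": _tile([61.9, 114.9]),
            "F": _tile([53.0, 97.2]),
        },
    }
)


def discretize_clinical(
    cohort: Cohort, table: DiscretizationTable = CLINICAL_DISCRETIZATION
) -> Cohort:
    """Replace each tabled numeric variable by its 1-based category index.

    Variables absent from the table pass through unchanged.  Output features
    are re-declared ordinal.
    """
    X = cohort.X.copy()
    schema = []
    for s in cohort.schema:
        if s.name in table.bins:
            cats = table.categorize(s.name, X[s.name].to_numpy(), cohort.sex)
            X[s.name] = cats
            n_cat = max(
                len(v)
                for v in (
                    table.bins[s.name].values()
                    if isinstance(table.bins[s.name], dict)
                    else [table.bins[s.name]]
                )
            )
            schema.append(
                FeatureSpec(s.name, "ordinal", s.units, s.sex_specific, tuple(range(1, n_cat + 1)))
            )
        else:
            schema.append(s)
    return Cohort(X, cohort.y, schema, cohort.sex)
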