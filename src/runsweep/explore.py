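"""Headless analytics over the runsInfo table.

Replaces interactive brushing with composable :class:`Filter` objects
(conjunctions of per-column predicates), provides histogram summaries,
Pareto-frontier extraction for multi-objective trade-offs (e.g. ROC
true-positive vs false-positive counts), and a direction-aware min-max
normalized mean of quality metrics for ranking runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Filter",
    "ParetoSpec",
    "HistogramSummary",
    "MetricDirectionRegistry",
    "DEFAULT_METRIC_DIRECTIONS",
    "apply_filters",
    "histogram",
    "pareto_front",
    "normalized_mean_quality",
]


@dataclass(frozen=True)
class Filter:
    """Keep runs whose ``column`` value lies in a closed numeric interval
    (``lo``/``hi``) or in a categorical ``values`` subset."""

    column: str
    lo: float | None = None
    hi: float | None = None
    values: tuple | None = None

    def __post_init__(self) -> None:
        numeric = self.lo is not None or self.hi is not None
        if numeric and self.values is not None:
            raise ValueError(f"filter on {self.column!r}: interval and value set are exclusive")
        if not numeric and self.values is None:
            raise ValueError(f"filter on {self.column!r}: empty predicate")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ValueError(f"filter on {self.column!r}: lo {self.lo} > hi {self.hi}")
        if self.values is not None and len(self.values) == 0:
            raise ValueError(f"filter on {self.column!r}: value subset is empty")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        col = df[self.column]
        if self.values is not None:
            return col.isin(self.values).to_numpy()
        m = np.ones(len(df), dtype=bool)
        if self.lo is not None:
            m &= (col >= self.lo).to_numpy()
        if self.hi is not None:
            m &= (col <= self.hi).to_numpy()
        return m & col.notna().to_numpy()

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"column": self.column}
        if self.values is not None:
            d["values"] = list(self.values)
        else:
            if self.lo is not None:
                d["lo"] = self.lo
            if self.hi is not None:
                d["hi"] = self.hi
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "Filter":
        values = d.get("values")
        return cls(
            column=d["column"],
            lo=d.get("lo"),
            hi=d.get("hi"),
            values=tuple(values) if values is not None else None,
        )


def apply_filters(runs_info: pd.DataFrame, filters: Iterable[Filter]) -> np.ndarray:
    """Conjunction of filter predicates; returns matching run_ids sorted
    ascending. An empty filter list keeps every run."""
    mask = np.ones(len(runs_info), dtype=bool)
    for f in filters:
        if f.column not in runs_info.columns:
            raise KeyError(
                f"unknown column {f.column!r}; available: {sorted(runs_info.columns)}"
            )
        mask &= f.mask(runs_info)
    ids = runs_info.loc[mask, "run_id"].to_numpy()
    return np.sort(ids)


@dataclass
class HistogramSummary:
    """Counts per bin (numeric: ``edges`` has len(counts)+1 entries) or per
    category (``categories`` aligned with counts)."""

    column: str
    counts: np.ndarray
    edges: np.ndarray | None = None
    categories: list | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def histogram(runs_info: pd.DataFrame, column: str, bins: int | None = None) -> HistogramSummary:
    """Histogram of one runsInfo column.

    Numeric columns use Sturges' rule unless ``bins`` is given; categorical
    columns count every distinct value. Missing values are dropped; the
    counts always sum to the number of non-missing rows.
    """
    if column not in runs_info.columns:
        raise KeyError(f"unknown column {column!r}; available: {sorted(runs_info.columns)}")
    col = runs_info[column].dropna()
    if len(col) == 0:
        logger.warning("histogram of %r: all values missing", column)
        return HistogramSummary(column=column, counts=np.zeros(0, dtype=int))
    if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
        x = col.to_numpy(dtype=float)
        if bins is None:
            bins = int(np.ceil(np.log2(len(x))) + 1) if len(x) > 1 else 1  # Sturges
        counts, edges = np.histogram(x, bins=bins)
        return HistogramSummary(column=column, counts=counts, edges=edges)
    vc = col.value_counts().sort_index(key=lambda idx: idx.map(str))
    return HistogramSummary(
        column=column, counts=vc.to_numpy(), categories=list(vc.index)
    )


# ---------------------------------------------------------------------------
# Pareto analysis


@dataclass(frozen=True)
class ParetoSpec:
    """Optimization directions over numeric runsInfo columns: at least two
    (column, direction) axes with direction in {minimize, maximize}."""

    axes: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.axes) < 2:
            raise ValueError("a Pareto spec needs at least 2 axes")
        for col, direction in self.axes:
            if direction not in ("minimize", "maximize"):
                raise ValueError(f"axis {col!r}: direction must be minimize or maximize")

    @property
    def columns(self) -> list[str]:
        return [c for c, _ in self.axes]

    def to_dict(self) -> dict:
        return {"axes": [[c, d] for c, d in self.axes]}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParetoSpec":
        return cls(axes=tuple((c, drc) for c, drc in d["axes"]))


def pareto_front(runs_info: pd.DataFrame, spec: ParetoSpec) -> np.ndarray:
    """Run IDs of the non-dominated set under weak dominance.

    A run is dominated iff some other run is at least as good on every axis
    and strictly better on at least one; exact ties on all axes keep both
    runs. Runs with a missing value on any axis are excluded beforehand.
    """
    cols = spec.columns
    df = runs_info.dropna(subset=cols)
    if len(df) == 0:
        return np.array([], dtype=int)
    # orient all axes toward "larger is better"
    M = np.column_stack(
        [
            df[c].to_numpy(dtype=float) * (1.0 if d == "maximize" else -1.0)
            for c, d in spec.axes
        ]
    )
    n = len(M)
    keep = np.ones(n, dtype=bool)
    # vectorized pairwise dominance, row-block at a time
    for i in range(n):
        if not keep[i]:
            continue
        ge = (M >= M[i]).all(axis=1)
        gt = (M > M[i]).any(axis=1)
        if np.any(ge & gt):
            keep[i] = False
    ids = df.loc[keep, "run_id"].to_numpy()
    return np.sort(ids)


# ---------------------------------------------------------------------------
# quality aggregation


#: default orientation of the bundled clustering validity indices: larger
#: Calinski-Harabasz / Silhouette / Gap indicate better-separated clusters,
#: while Davies-Bouldin and S_Dbw are dispersion ratios where smaller wins.
DEFAULT_METRIC_DIRECTIONS: dict[str, bool] = {
    "calinski_harabasz": True,
    "silhouette": True,
    "davies_bouldin": False,
    "gap": True,
    "s_dbw": False,
}


@dataclass
class MetricDirectionRegistry:
    """Maps metric column name -> higher_is_better flag; overridable."""

    directions: dict[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_DIRECTIONS)
    )

    def higher_is_better(self, metric: str) -> bool:
        if metric not in self.directions:
            raise KeyError(
                f"metric {metric!r} not registered; known: {sorted(self.directions)}"
            )
        return self.directions[metric]

    def register(self, metric: str, higher_is_better: bool) -> None:
        self.directions[metric] = higher_is_better


def normalized_mean_quality(
    runs_info: pd.DataFrame,
    metric_columns: Sequence[str],
    registry: MetricDirectionRegistry | None = None,
    out_column: str = "mean_normalized_quality",
) -> pd.Series:
    """Direction-aware min-max aggregate of several quality metrics.

    Each metric is min-max normalized to [0, 1] over its non-missing runs,
    inverted when lower is better, then averaged per run over the metrics
    available for that run. A constant metric column carries no ranking
    information and is mapped to 0.5 everywhere (with a warning).
    """
    registry = registry or MetricDirectionRegistry()
    normalized = {}
    for col in metric_columns:
        if col not in runs_info.columns:
            raise KeyError(f"metric column {col!r} not in runsInfo")
        x = runs_info[col].to_numpy(dtype=float)
        finite = np.isfinite(x)
        if not finite.any():
            logger.warning("metric %r is entirely missing", col)
            normalized[col] = np.full(len(x), np.nan)
            continue
        lo, hi = np.nanmin(x[finite]), np.nanmax(x[finite])
        if hi == lo:
            logger.warning("metric %r is constant; normalized to 0.5", col)
            z = np.where(finite, 0.5, np.nan)
        else:
            z = (x - lo) / (hi - lo)
        if not registry.higher_is_better(col):
            z = 1.0 - z
        normalized[col] = z
    Z = np.column_stack([normalized[c] for c in metric_columns])
    with np.errstate(invalid="ignore"):
        agg = np.nanmean(Z, axis=1)
    return pd.Series(agg, index=runs_info.index, name=out_column)


def load_filters(path: str | Path) -> list[Filter]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, Mapping):
        data = data.get("filters", [])
    return [Filter.from_dict(d) for d in data]
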