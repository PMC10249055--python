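"""Derivation passes: summarize each run's raw output into runsInfo columns.

A sweep leaves one output table (or several) per run on disk; analysis needs
one row of scalars per run. Each :class:`DerivationPass` applies one
summarization method to one output table and appends the resulting columns
to the runsInfo table. Column names follow fixed templates so downstream
filters and plots can reference them predictably:

===================== ==========================================
method                columns appended
===================== ==========================================
mean/sum/median/...   ``<fn>_<column>``
n_class_labels        ``Num(<table>)``
mode_class_labels     ``mode_<column>``
count_per_class_label ``n(<column> = <label>)`` per observed label
gt_comparison         ``n(<pred> = <P> & <gt> = <G>)``, six cells
dimred_{pca,mds,tsne} ``<method>1(<table>)``, ``<method>2(<table>)``
take_first_row        the table's own column names
none                  nothing
===================== ==========================================

Runs with a missing or unreadable output file yield missing values (NA),
never silent zeros. Re-applying a pass replaces its columns instead of
duplicating them, so derivation plans are idempotent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .embedding import embed_2d
from .sampler import RunsSession

__all__ = [
    "DerivationPass",
    "DerivedColumns",
    "DerivationError",
    "derive_aggregate",
    "derive_class_label_stats",
    "derive_gt_comparison",
    "derive_dimred",
    "derive_take_first_row",
    "apply_passes",
    "load_derivation_plan",
]

AGGREGATE_FNS = ("mean", "sum", "median", "min", "max")
CLASS_LABEL_FNS = ("n_class_labels", "mode_class_labels", "count_per_class_label")
DIMRED_METHODS = {"dimred_pca": "pca", "dimred_mds": "mds", "dimred_tsne": "tsne"}
METHODS = (
    *AGGREGATE_FNS,
    *CLASS_LABEL_FNS,
    "gt_comparison",
    *DIMRED_METHODS,
    "take_first_row",
    "none",
)

PLAN_FILE = "derivation_plan.json"
#: columns a pass may never overwrite
_PROTECTED = ("run_id", "status", "duration_seconds")


class DerivationError(ValueError):
    """Raised when a pass is invalid for the session it is applied to."""


@dataclass(frozen=True)
class DerivationPass:
    """One summarization method applied to one output table.

    ``column`` selects the data column for aggregate/label methods;
    ``columns`` selects the numeric columns for dimensionality reduction
    (None = all numeric); ``gt_column`` names the ground-truth column of the
    *input* table for gt_comparison; ``seed`` feeds stochastic embeddings.
    """

    method: str
    table: str | None = None
    column: str | None = None
    columns: tuple[str, ...] | None = None
    gt_column: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise DerivationError(f"unknown derivation method {self.method!r}")
        if self.method == "none":
            if any(v is not None for v in (self.table, self.column, self.columns, self.gt_column)):
                raise DerivationError("method 'none' takes no other fields")
        elif self.table is None:
            raise DerivationError(f"method {self.method!r} requires a table name")
        if self.method in (*AGGREGATE_FNS, *CLASS_LABEL_FNS) and self.column is None:
            raise DerivationError(f"method {self.method!r} requires a column name")
        if self.method == "gt_comparison" and (self.column is None or self.gt_column is None):
            raise DerivationError("gt_comparison requires a prediction column and a gt_column")

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"method": self.method}
        for key in ("table", "column", "gt_column"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        if self.columns is not None:
            d["columns"] = list(self.columns)
        if self.seed:
            d["seed"] = self.seed
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "DerivationPass":
        cols = d.get("columns")
        return cls(
            method=d["method"],
            table=d.get("table"),
            column=d.get("column"),
            columns=tuple(cols) if cols is not None else None,
            gt_column=d.get("gt_column"),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class DerivedColumns:
    """Ordered column labels plus per-run values aligned to run_id order."""

    labels: list[str]
    values: pd.DataFrame  # columns == labels, one row per run

    def __post_init__(self) -> None:
        assert list(self.values.columns) == list(self.labels)


def load_derivation_plan(path: str | Path) -> list[DerivationPass]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, Mapping):
        data = data.get("passes", [])
    return [DerivationPass.from_dict(d) for d in data]


# ---------------------------------------------------------------------------
# helpers


def _iter_run_tables(session: RunsSession, table: str):
    """Yield (run_id, DataFrame-or-None) in runsInfo row order."""
    for run_id in session.runs_info["run_id"]:
        yield int(run_id), session.output_table(table, int(run_id))


def _format_label(value: Any) -> str:
    """Render a data value inside a derived-column name."""
    if isinstance(value, (bool, np.bool_)):
        return "TRUE" if value else "FALSE"
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, (float, np.floating)) and float(value) == int(value):
        return str(int(value))
    return str(value)


def _frame(labels: Sequence[str], rows: list[list], index) -> DerivedColumns:
    df = pd.DataFrame(rows, columns=list(labels), index=index)
    return DerivedColumns(labels=list(labels), values=df)


# ---------------------------------------------------------------------------
# the derivation methods


def derive_aggregate(session: RunsSession, table: str, column: str, fn: str) -> DerivedColumns:
    """Aggregate a numeric column of each run's table into ``<fn>_<column>``."""
    if fn not in AGGREGATE_FNS:
        raise DerivationError(f"unknown aggregate {fn!r} (legal: {AGGREGATE_FNS})")
    label = f"{fn}_{column}"
    rows = []
    for run_id, df in _iter_run_tables(session, table):
        if df is None or column not in df.columns or len(df) == 0:
            rows.append([np.nan])
            continue
        col = df[column]
        if not pd.api.types.is_numeric_dtype(col):
            raise DerivationError(
                f"column {column!r} of table {table!r} is not numeric (run {run_id})"
            )
        rows.append([float(getattr(col, fn)())])
    return _frame([label], rows, session.runs_info.index)


def derive_class_label_stats(
    session: RunsSession, table: str, column: str, fn: str
) -> DerivedColumns:
    """Summaries of a categorical label column.

    n_class_labels counts distinct labels per run (``Num(<table>)``);
    mode_class_labels takes the most frequent label (``mode_<column>``);
    count_per_class_label emits one ``n(<column> = <label>)`` column per
    label observed in *any* run, zero-filled where a run lacks that label so
    the runsInfo table stays rectangular.
    """
    if fn not in CLASS_LABEL_FNS:
        raise DerivationError(f"unknown class-label method {fn!r}")
    per_run: list[tuple[int, pd.Series | None]] = []
    universe: list = []
    seen = set()
    for run_id, df in _iter_run_tables(session, table):
        if df is None or column not in df.columns or len(df) == 0:
            per_run.append((run_id, None))
            continue
        counts = df[column].value_counts(dropna=True)
        per_run.append((run_id, counts))
        for label in counts.index:
            if label not in seen:
                seen.add(label)
                universe.append(label)
    if fn == "n_class_labels":
        rows = [[np.nan if c is None else float(len(c))] for _, c in per_run]
        return _frame([f"Num({table})"], rows, session.runs_info.index)
    if fn == "mode_class_labels":
        rows = [[None if c is None or c.empty else c.index[0]] for _, c in per_run]
        return _frame([f"mode_{column}"], rows, session.runs_info.index)
    # count_per_class_label: label universe is the union over all runs
    universe_sorted = sorted(universe, key=_format_label)
    labels = [f"n({column} = {_format_label(v)})" for v in universe_sorted]
    rows = []
    for _, counts in per_run:
        if counts is None:
            rows.append([np.nan] * len(labels))
        else:
            rows.append([float(counts.get(v, 0)) for v in universe_sorted])
    return _frame(labels, rows, session.runs_info.index)


_TRUTHY = {True, "TRUE", "True", "true", 1}
_FALSY = {False, "FALSE", "False", "false", 0}


def _as_bool(value: Any, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if value in _TRUTHY:
        return True
    if value in _FALSY:
        return False
    raise DerivationError(f"{where}: value {value!r} is not boolean")


def _as_ternary(value: Any) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, str) and value.upper() == "NA":
        return "NA"
    return "TRUE" if _as_bool(value, "ground truth column") else "FALSE"


def derive_gt_comparison(
    session: RunsSession, table: str, pred_column: str, gt_column: str
) -> DerivedColumns:
    """Cross-tabulate a boolean prediction against a {TRUE, FALSE, NA} truth.

    Appends six count columns, one per (prediction, truth) cell, named
    ``n(<pred> = <P> & <gt> = <G>)``; their per-run sum equals the row count
    of the compared table. With TRUE meaning a positive call, the
    (TRUE, TRUE) cell is the true-positive count and (TRUE, FALSE) the
    false-positive count; the NA cells hold rows whose truth is unknown.
    """
    if session.input_table is None:
        raise DerivationError("gt_comparison needs the session's input table")
    if gt_column not in session.input_table.columns:
        raise DerivationError(
            f"ground-truth column {gt_column!r} not in input table "
            f"(available: {list(session.input_table.columns)})"
        )
    truth = np.array([_as_ternary(v) for v in session.input_table[gt_column]])
    cells = [(p, g) for p in ("TRUE", "FALSE") for g in ("TRUE", "FALSE", "NA")]
    labels = [f"n({pred_column} = {p} & {gt_column} = {g})" for p, g in cells]
    rows = []
    for run_id, df in _iter_run_tables(session, table):
        if df is None or pred_column not in df.columns:
            rows.append([np.nan] * 6)
            continue
        if len(df) != len(truth):
            raise DerivationError(
                f"run {run_id}: table {table!r} has {len(df)} rows but the input "
                f"table has {len(truth)}"
            )
        pred = np.array(
            ["TRUE" if _as_bool(v, f"run {run_id} column {pred_column!r}") else "FALSE"
             for v in df[pred_column]]
        )
        rows.append([float(np.sum((pred == p) & (truth == g))) for p, g in cells])
    return _frame(labels, rows, session.runs_info.index)


def derive_dimred(
    session: RunsSession,
    table: str,
    columns: Sequence[str] | None,
    method: str,
    seed: int = 0,
) -> DerivedColumns:
    """Embed the *runs* into 2-D from their flattened output tables.

    Each run's selected numeric columns are flattened to one feature vector;
    the runs x features matrix is reduced to two coordinates per run,
    appended as ``<method>1(<table>)`` / ``<method>2(<table>)``. Runs with
    missing outputs get NA coordinates. All present runs must produce
    equal-length vectors.
    """
    if method in DIMRED_METHODS:
        method = DIMRED_METHODS[method]
    if method not in ("pca", "mds", "tsne"):
        raise DerivationError(f"unknown dimred method {method!r}")
    vectors: dict[int, np.ndarray] = {}
    length = None
    for run_id, df in _iter_run_tables(session, table):
        if df is None:
            continue
        use = df[list(columns)] if columns else df.select_dtypes(include=[np.number])
        vec = use.to_numpy(dtype=float).ravel()
        if length is None:
            length = vec.size
        elif vec.size != length:
            raise DerivationError(
                f"run {run_id}: flattened output has length {vec.size}, expected {length}"
            )
        vectors[run_id] = vec
    if len(vectors) < 2:
        raise DerivationError("dimensionality reduction needs at least 2 complete runs")
    ids = [int(r) for r in session.runs_info["run_id"]]
    present = [r for r in ids if r in vectors]
    X = np.vstack([vectors[r] for r in present])
    coords = embed_2d(X, method, seed=seed)
    lookup = {r: coords[i] for i, r in enumerate(present)}
    labels = [f"{method}1({table})", f"{method}2({table})"]
    rows = [list(lookup[r]) if r in lookup else [np.nan, np.nan] for r in ids]
    return _frame(labels, rows, session.runs_info.index)


def derive_take_first_row(session: RunsSession, table: str) -> DerivedColumns:
    """Adopt the first row of each run's table under the table's own column
    names. This is the hook by which model apps export self-computed derived
    output (e.g. a one-row table of quality metrics)."""
    labels: list[str] | None = None
    per_run: list[tuple[int, pd.DataFrame | None]] = list(_iter_run_tables(session, table))
    for _, df in per_run:
        if df is not None and len(df.columns):
            labels = list(df.columns)
            break
    if labels is None:
        raise DerivationError(f"no run produced a readable table {table!r}")
    rows = []
    for _, df in per_run:
        if df is None or len(df) == 0:
            rows.append([np.nan] * len(labels))
        else:
            rows.append([df.iloc[0].get(c, np.nan) for c in labels])
    return _frame(labels, rows, session.runs_info.index)


# ---------------------------------------------------------------------------
# pass orchestration


def _run_pass(session: RunsSession, p: DerivationPass) -> DerivedColumns | None:
    if p.method == "none":
        return None
    if p.method in AGGREGATE_FNS:
        return derive_aggregate(session, p.table, p.column, p.method)
    if p.method in CLASS_LABEL_FNS:
        return derive_class_label_stats(session, p.table, p.column, p.method)
    if p.method == "gt_comparison":
        return derive_gt_comparison(session, p.table, p.column, p.gt_column)
    if p.method in DIMRED_METHODS:
        return derive_dimred(session, p.table, p.columns, p.method, seed=p.seed)
    if p.method == "take_first_row":
        return derive_take_first_row(session, p.table)
    raise DerivationError(f"unhandled method {p.method!r}")  # pragma: no cover


def apply_passes(
    session: RunsSession, passes: Iterable[DerivationPass], persist: bool = True
) -> pd.DataFrame:
    """Apply passes in order and append their columns to runsInfo.

    Re-running a pass replaces its columns (derivation is idempotent);
    colliding with a parameter or bookkeeping column is an error. When
    ``persist`` is true, runsInfo.txt is rewritten atomically and the plan is
    recorded beside it for provenance. Raw per-run output files are never
    touched.
    """
    passes = list(passes)
    info = session.runs_info.copy()
    protected = set(_PROTECTED) | set(session.parameter_columns)
    for p in passes:
        derived = _run_pass(session, p)
        if derived is None:
            continue
        clash = protected & set(derived.labels)
        if clash:
            raise DerivationError(
                f"derived columns {sorted(clash)} collide with parameter/bookkeeping columns"
            )
        info = info.drop(columns=[c for c in derived.labels if c in info.columns])
        for label in derived.labels:
            info[label] = derived.values[label].to_numpy()
    if persist:
        session.write_runs_info(info)
        plan_path = session.root / PLAN_FILE
        plan_path.write_text(json.dumps([p.to_dict() for p in passes], indent=2) + "\n")
        return session.runs_info
    session.runs_info = info
    return info
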