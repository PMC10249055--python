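"""Static report export: the headless stand-in for an interactive workspace.

Given a loaded session and a JSON-style config, writes a directory of PNG
plots (scatter plots with optional categorical color and seeded jitter,
per-column histograms), TSV tables (the filtered runsInfo, the Pareto front)
and an ``index.html`` linking everything together.

Config keys (all optional)::

    filters:    [{column, lo/hi or values}, ...]   applied to every artifact
    scatter:    [{x, y, color?, x_max?, y_max?, jitter?}, ...]
    histograms: [column, ...] or "all"
    pareto:     {axes: [[column, minimize|maximize], ...]}
    selected_runs: [run_id, ...]   thumbnails of these runs' images
"""

from __future__ import annotations

import html
import logging
import shutil
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .explore import Filter, ParetoSpec, apply_filters, histogram, pareto_front
from .sampler import RunsSession, write_table

logger = logging.getLogger(__name__)

__all__ = ["export_report"]


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in str(text))


def _scatter(df: pd.DataFrame, cfg: Mapping[str, Any], out: Path, jitter_seed: int) -> str:
    import matplotlib.pyplot as plt

    x, y = cfg["x"], cfg["y"]
    color = cfg.get("color")
    fig, ax = plt.subplots(figsize=(5, 4))
    xv = df[x].to_numpy()
    yv = df[y].to_numpy()
    if cfg.get("jitter"):
        # render-time only; stored data is never jittered
        rng = np.random.default_rng(jitter_seed)
        if np.issubdtype(np.asarray(xv).dtype, np.number):
            xv = xv + rng.normal(0, cfg["jitter"], len(xv))
        if np.issubdtype(np.asarray(yv).dtype, np.number):
            yv = yv + rng.normal(0, cfg["jitter"], len(yv))
    if color is not None and color in df.columns:
        series = df[color]
        if pd.api.types.is_numeric_dtype(series) and not pd.api.types.is_bool_dtype(series):
            sc = ax.scatter(xv, yv, c=series, s=14, cmap="viridis")
            fig.colorbar(sc, ax=ax, label=color)
        else:
            for value, grp_idx in series.groupby(series).groups.items():
                idx = df.index.get_indexer(grp_idx)
                ax.scatter(np.asarray(xv)[idx], np.asarray(yv)[idx], s=14, label=str(value))
            ax.legend(title=color, fontsize=7)
    else:
        ax.scatter(xv, yv, s=14)
    if cfg.get("x_max") is not None:
        ax.set_xlim(right=cfg["x_max"])
        ax.set_xlim(left=0)
    if cfg.get("y_max") is not None:
        ax.set_ylim(top=cfg["y_max"])
        ax.set_ylim(bottom=0)
    ax.set_xlabel(x)
    ax.set_ylabel(y)
    fig.tight_layout()
    name = f"scatter_{_slug(x)}_vs_{_slug(y)}.png"
    fig.savefig(out / name, dpi=96)
    plt.close(fig)
    return name


def _histogram_png(df: pd.DataFrame, column: str, out: Path) -> str | None:
    import matplotlib.pyplot as plt

    summary = histogram(df, column)
    if summary.total == 0:
        logger.warning("skipping histogram of all-missing column %r", column)
        return None
    fig, ax = plt.subplots(figsize=(4, 3))
    if summary.edges is not None:
        widths = np.diff(summary.edges)
        ax.bar(summary.edges[:-1], summary.counts, width=widths, align="edge")
    else:
        ax.bar([str(c) for c in summary.categories], summary.counts)
        ax.tick_params(axis="x", rotation=45, labelsize=7)
    ax.set_xlabel(column)
    ax.set_ylabel("runs")
    fig.tight_layout()
    name = f"hist_{_slug(column)}.png"
    fig.savefig(out / name, dpi=96)
    plt.close(fig)
    return name


def export_report(
    session: RunsSession, config: Mapping[str, Any], out_dir: str | Path
) -> Path:
    """Write the report described by ``config`` under ``out_dir``.

    Always writes ``runs_filtered.tsv`` (the filtered runsInfo) and
    ``index.html``; scatter plots, histograms, the Pareto-front table and
    run-image thumbnails are emitted when configured. Returns ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    filters = [Filter.from_dict(f) for f in config.get("filters", [])]
    ids = apply_filters(session.runs_info, filters)
    df = session.runs_info[session.runs_info["run_id"].isin(ids)]
    write_table(df, out / "runs_filtered.tsv")
    items: list[tuple[str, str]] = [("Filtered runs table", "runs_filtered.tsv")]

    jitter_seed = int(config.get("jitter_seed", 0))
    for cfg in config.get("scatter", []):
        missing = [c for c in (cfg["x"], cfg["y"], cfg.get("color")) if c and c not in df.columns]
        if missing:
            raise KeyError(f"scatter config references unknown columns {missing}")
        if len(df) == 0:
            continue
        items.append((f"Scatter {cfg['x']} vs {cfg['y']}", _scatter(df, cfg, out, jitter_seed)))

    hist_cols = config.get("histograms", [])
    if hist_cols == "all":
        hist_cols = [c for c in df.columns if c != "run_id"]
    for col in hist_cols:
        if col not in df.columns:
            raise KeyError(f"histogram config references unknown column {col!r}")
        if len(df) == 0:
            continue
        name = _histogram_png(df, col, out)
        if name:
            items.append((f"Histogram of {col}", name))

    if config.get("pareto"):
        spec = ParetoSpec.from_dict(config["pareto"])
        missing = [c for c in spec.columns if c not in df.columns]
        if missing:
            raise KeyError(f"pareto config references unknown columns {missing}")
        front_ids = pareto_front(df, spec)
        front = df[df["run_id"].isin(front_ids)]
        write_table(front, out / "pareto_front.tsv")
        items.append(("Pareto front", "pareto_front.tsv"))

    for run_id in config.get("selected_runs", []):
        src = session.image_path(int(run_id))
        dst = out / f"run_{run_id}.png"
        if src.exists():
            shutil.copyfile(src, dst)
            items.append((f"Run {run_id} output", dst.name))
        else:
            logger.warning("image for run %s is missing; placeholder written", run_id)
            dst.with_suffix(".txt").write_text(f"image for run {run_id} missing\n")
            items.append((f"Run {run_id} output (missing)", dst.with_suffix(".txt").name))

    lines = ["<html><head><title>sweep report</title></head><body>",
             f"<h1>Sweep report</h1><p>{len(df)} runs after filtering.</p><ul>"]
    for title, name in items:
        lines.append(f'<li><a href="{html.escape(name)}">{html.escape(title)}</a></li>')
    lines.append("</ul></body></html>")
    (out / "index.html").write_text("\n".join(lines) + "\n")
    return out
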