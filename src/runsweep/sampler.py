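"""Uniform parameter sampling and the on-disk runs-directory layout.

A sweep session executes a model app once per randomly drawn parameter
combination and persists everything needed for later analysis in a flat,
tool-agnostic directory::

    <out_dir>/
        input.txt            # the app's input data table (TSV)
        paramInfo.txt        # parameter name/type table
        runsInfo.txt         # one row per run: run_id, parameters, status
        sampling_spec.json   # the sweep specification (reproducibility)
        manifest.json        # the app manifest (reproducibility)
        runs/                # <TableName>_<runID>.txt output tables
        images/              # <runID>.png image outputs

The same layout can be produced by external tools; :func:`load_runs_directory`
only requires ``runsInfo.txt`` to be present.

Randomness is counter-based: the generator for draw ``i`` depends only on
``(spec.seed, i)``, so an interrupted session resumed later reproduces the
exact combination stream of an uninterrupted one.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd

from .manifest import (
    AppManifest,
    ManifestError,
    SamplingSpec,
    load_sampling_spec,
    parse_manifest,
    validate_sampling_spec,
)

__all__ = [
    "AppResult",
    "RunsSession",
    "sample_combination",
    "run_session",
    "resume_session",
    "load_runs_directory",
    "read_table",
    "write_table",
    "format_cell",
]

RUNS_INFO = "runsInfo.txt"
PARAM_INFO = "paramInfo.txt"
INPUT_TABLE = "input.txt"
SPEC_FILE = "sampling_spec.json"
MANIFEST_FILE = "manifest.json"

#: bookkeeping columns written by the session runner, in order
_STATUS_COLUMNS = ("status", "duration_seconds")


@dataclass
class AppResult:
    """What a model app returns for one run: named tables plus an optional
    image (a matplotlib Figure or an HxWx3 uint8 array)."""

    tables: Mapping[str, pd.DataFrame]
    image: Any = None


# a model app is any callable (input_table, params) -> AppResult
ModelApp = Callable[[pd.DataFrame, Mapping[str, Any]], AppResult]


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    tmp = Path(str(path) + ".tmp")
    df.to_csv(tmp, sep="\t", index=False, na_rep="NA")
    tmp.replace(path)


def format_cell(value: Any) -> str:
    """Serialize one runsInfo cell. Booleans use TRUE/FALSE, matching the
    conventions of the table files."""
    if isinstance(value, (bool, np.bool_)):
        return "TRUE" if value else "FALSE"
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "NA"
    if isinstance(value, (float, np.floating)):
        return repr(float(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    return str(value)


# ---------------------------------------------------------------------------
# sampling


def _rng_for_draw(seed: int, draw_index: int) -> np.random.Generator:
    # counter-based stream: each draw owns an independent child generator
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(draw_index,)))


def sample_combination(manifest: AppManifest, spec: SamplingSpec, draw_index: int) -> dict:
    """Draw one parameter combination.

    Integer ranges are sampled uniformly on the closed interval [lo, hi],
    doubles uniformly on [lo, hi], boolean/categorical parameters uniformly
    over their enabled set; constants pass through. Reproducible from
    ``(spec.seed, draw_index)`` alone.
    """
    if draw_index < 0:
        raise ValueError("draw_index must be non-negative")
    rng = _rng_for_draw(spec.seed, draw_index)
    values: dict[str, Any] = {}
    for p in manifest.parameters:
        d = spec.directive(p.name)
        if d.mode == "constant":
            values[p.name] = d.value
        elif d.mode == "numeric_range":
            if p.kind == "integer":
                values[p.name] = int(rng.integers(int(d.lo), int(d.hi) + 1))
            else:
                values[p.name] = float(rng.uniform(d.lo, d.hi))
        else:  # boolean_set / categorical_set
            items = tuple(d.enabled_items or ())
            values[p.name] = items[int(rng.integers(0, len(items)))]
    return values


# ---------------------------------------------------------------------------
# session execution


def _save_image(image: Any, path: Path) -> None:
    if hasattr(image, "savefig"):  # matplotlib Figure
        image.savefig(path, dpi=72)
        import matplotlib.pyplot as plt

        plt.close(image)
    else:
        from PIL import Image

        arr = np.asarray(image)
        Image.fromarray(arr).save(path)


def _execute_runs(
    root: Path,
    app: ModelApp,
    input_table: pd.DataFrame,
    manifest: AppManifest,
    spec: SamplingSpec,
    first_id: int,
    n_runs: int,
    write_header: bool,
) -> None:
    runs_dir = root / "runs"
    images_dir = root / "images"
    runs_dir.mkdir(exist_ok=True)
    images_dir.mkdir(exist_ok=True)
    columns = ["run_id", *manifest.parameter_names, *_STATUS_COLUMNS]
    mode = "w" if write_header else "a"
    with open(root / RUNS_INFO, mode, encoding="utf-8") as fh:
        if write_header:
            fh.write("\t".join(columns) + "\n")
            fh.flush()
        for i in range(first_id, first_id + n_runs):
            values = sample_combination(manifest, spec, i)
            t0 = time.perf_counter()
            status = "ok"
            try:
                result = app(input_table, values)
            except KeyboardInterrupt:
                break
            except Exception:
                result, status = None, "failed"
            duration = time.perf_counter() - t0
            if result is not None:
                missing = set(manifest.output_tables) - set(result.tables)
                if missing:
                    raise ManifestError(
                        f"app {manifest.app_name!r} did not return declared "
                        f"tables {sorted(missing)}"
                    )
                for name in manifest.output_tables:
                    write_table(result.tables[name], runs_dir / f"{name}_{i}.txt")
                if manifest.emits_image and result.image is not None:
                    _save_image(result.image, images_dir / f"{i}.png")
            row = [str(i), *(format_cell(values[n]) for n in manifest.parameter_names),
                   status, repr(round(duration, 6))]
            fh.write("\t".join(row) + "\n")
            fh.flush()


def run_session(
    app: ModelApp,
    input_table: pd.DataFrame,
    manifest: AppManifest,
    spec: SamplingSpec,
) -> "RunsSession":
    """Execute a fresh sweep session into ``spec.out_dir``.

    Run IDs are assigned sequentially from 0. An app exception marks that
    run as failed (status column) and the session continues; an interrupt
    leaves a loadable partial session.
    """
    validate_sampling_spec(manifest, spec)
    if not spec.out_dir:
        raise ManifestError("spec.out_dir must be set for run_session")
    root = Path(spec.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    write_table(input_table, root / INPUT_TABLE)
    param_info = pd.DataFrame(
        {"name": manifest.parameter_names, "type": [p.kind for p in manifest.parameters]}
    )
    write_table(param_info, root / PARAM_INFO)
    manifest.to_json(root / MANIFEST_FILE)
    spec.to_json(root / SPEC_FILE)
    _execute_runs(root, app, input_table, manifest, spec,
                  first_id=0, n_runs=spec.n_runs, write_header=True)
    return load_runs_directory(root)


def resume_session(path: str | Path, app: ModelApp, additional_runs: int) -> "RunsSession":
    """Append ``additional_runs`` runs to an existing session.

    New run IDs continue from the maximum existing ID + 1 and, because
    sampling is counter-based, the combined combination stream equals that
    of a single uninterrupted session with the same seed.
    """
    root = Path(path)
    spec_path = root / SPEC_FILE
    if not spec_path.exists():
        raise FileNotFoundError(
            f"cannot resume: {spec_path} is missing (session was not written by this package?)"
        )
    manifest_path = root / MANIFEST_FILE
    if not manifest_path.exists():
        raise FileNotFoundError(f"cannot resume: {manifest_path} is missing")
    manifest = parse_manifest(manifest_path)
    spec = load_sampling_spec(spec_path)
    session = load_runs_directory(root)
    if session.input_table is None:
        raise FileNotFoundError(f"cannot resume: {root / INPUT_TABLE} is missing")
    next_id = 0 if session.runs_info.empty else int(session.runs_info["run_id"].max()) + 1
    if additional_runs > 0:
        _execute_runs(root, app, session.input_table, manifest, spec,
                      first_id=next_id, n_runs=additional_runs, write_header=False)
    return load_runs_directory(root)


# ---------------------------------------------------------------------------
# loading


@dataclass
class RunsSession:
    """A loaded runs directory: parsed tables plus lazy per-run accessors."""

    root: Path
    runs_info: pd.DataFrame
    param_info: pd.DataFrame | None = None
    input_table: pd.DataFrame | None = None
    manifest: AppManifest | None = None
    spec: SamplingSpec | None = None

    @property
    def run_ids(self) -> np.ndarray:
        return self.runs_info["run_id"].to_numpy()

    @property
    def parameter_columns(self) -> list[str]:
        if self.param_info is not None:
            return list(self.param_info["name"])
        return []

    def output_path(self, table: str, run_id: int) -> Path:
        return self.root / "runs" / f"{table}_{run_id}.txt"

    def has_output(self, table: str, run_id: int) -> bool:
        return self.output_path(table, run_id).exists()

    def output_table(self, table: str, run_id: int) -> pd.DataFrame | None:
        """Read one run's output table; None if the file is missing."""
        path = self.output_path(table, run_id)
        if not path.exists():
            return None
        return read_table(path)

    def image_path(self, run_id: int) -> Path:
        return self.root / "images" / f"{run_id}.png"

    def write_runs_info(self, df: pd.DataFrame) -> None:
        """Atomically replace runsInfo.txt and refresh the in-memory copy."""
        out = df.copy()
        tmp = self.root / (RUNS_INFO + ".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            fh.write("\t".join(map(str, out.columns)) + "\n")
            for _, row in out.iterrows():
                fh.write("\t".join(format_cell(v) for v in row) + "\n")
        tmp.replace(self.root / RUNS_INFO)
        self.runs_info = read_table(self.root / RUNS_INFO)


def load_runs_directory(path: str | Path) -> RunsSession:
    """Load a session from disk.

    ``runsInfo.txt`` is required; everything else (paramInfo, input table,
    spec, manifest, per-run files) is optional so that directories produced
    by external tools still load.
    """
    root = Path(path)
    info_path = root / RUNS_INFO
    if not info_path.exists():
        raise FileNotFoundError(f"not a runs directory: missing {info_path}")
    runs_info = read_table(info_path)
    if "run_id" not in runs_info.columns:
        raise ManifestError(f"{info_path} has no run_id column")
    if runs_info["run_id"].duplicated().any():
        raise ManifestError(f"{info_path} has duplicated run_ids")
    param_info = None
    if (root / PARAM_INFO).exists():
        param_info = read_table(root / PARAM_INFO)
    input_table = None
    if (root / INPUT_TABLE).exists():
        input_table = read_table(root / INPUT_TABLE)
    manifest = None
    if (root / MANIFEST_FILE).exists():
        manifest = parse_manifest(root / MANIFEST_FILE)
    spec = None
    if (root / SPEC_FILE).exists():
        spec = load_sampling_spec(root / SPEC_FILE)
    return RunsSession(
        root=root,
        runs_info=runs_info,
        param_info=param_info,
        input_table=input_table,
        manifest=manifest,
        spec=spec,
    )
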