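"""Minimal fully connected classifier for the hyperparameter-sweep demo.

A numpy MLP trained by mini-batch gradient descent on squared error against
+/-1 targets with a tanh output neuron (loss = mean((out - y)^2) / 2, so a
constant-zero predictor scores 0.5 and a perfect one 0). Hidden layers use
the selected activation; ``linear`` is the identity f(x) = x, which makes
the whole network an affine map regardless of depth -- the contrast that
the sweep analyses exploit.

Two entry points:

* :func:`mlp_model_app` -- the generic one-run model-app contract (trains
  for the ``epochs`` parameter, returns predictions + one-row metrics).
* :func:`run_mlp_session` -- the sweep driver used for hyperparameter
  studies: n random combinations, each trained once with metrics recorded
  at several epoch checkpoints, every checkpoint becoming its own record in
  the runsInfo table (``epoch`` is a recorded column). The directory it
  writes is the standard layout with derived metrics already present, i.e.
  the path otherwise taken by externally produced sweeps.
"""

from __future__ import annotations

import time
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ..manifest import AppManifest, ParameterSpec, default_sampling_spec
from ..sampler import (
    INPUT_TABLE,
    MANIFEST_FILE,
    PARAM_INFO,
    RUNS_INFO,
    SPEC_FILE,
    AppResult,
    RunsSession,
    format_cell,
    load_runs_directory,
    sample_combination,
    write_table,
)
from .playground import FEATURE_COLUMNS

__all__ = ["MLP_MANIFEST", "DEFAULT_CHECKPOINTS", "mlp_model_app", "train_mlp",
           "run_mlp_session", "default_mlp_sweep_spec"]

DEFAULT_CHECKPOINTS = (50, 100, 200, 400)

#: boolean feature-toggle parameter -> dataset column
FEATURE_PARAMS = {
    "use_X1": "X1",
    "use_X2": "X2",
    "use_X1sq": "X1^2",
    "use_X2sq": "X2^2",
    "use_X1X2": "X1*X2",
    "use_sinX1": "sin(X1)",
    "use_sinX2": "sin(X2)",
}
assert tuple(FEATURE_PARAMS.values()) == FEATURE_COLUMNS

MLP_MANIFEST = AppManifest(
    app_name="mlp",
    parameters=(
        ParameterSpec("n_layers", "integer", 1, min=0, max=6, label="Hidden layers"),
        ParameterSpec("n_neurons", "integer", 4, min=1, max=8,
                      label="Neurons per hidden layer"),
        *(
            ParameterSpec(name, "boolean", name in ("use_X1", "use_X2"),
                          label=f"enable feature {col}")
            for name, col in FEATURE_PARAMS.items()
        ),
        ParameterSpec("train_ratio", "double", 0.5, min=0.1, max=0.9,
                      label="Ratio of training to test data"),
        ParameterSpec("batch_size", "integer", 10, min=1, max=30),
        ParameterSpec("learning_rate", "double", 0.03, min=0.00001, max=10.0),
        ParameterSpec("activation", "categorical", "tanh",
                      items=("linear", "relu", "sigmoid", "tanh")),
        ParameterSpec("regularization", "categorical", "off",
                      items=("off", "L1", "L2")),
        ParameterSpec("regularization_rate", "double", 0.0, min=0.0, max=1.0),
        ParameterSpec("epochs", "integer", 50, min=1, max=400,
                      info="training epochs for single runs"),
        ParameterSpec("seed", "integer", 0, min=0, max=1_000_000),
    ),
    output_tables=("predictions", "metrics"),
    emits_image=True,
)

_ACTIVATIONS = {
    "linear": (lambda z: z, lambda z, a: np.ones_like(z)),
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "sigmoid": (lambda z: expit(z), lambda z, a: a * (1.0 - a)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a**2),
}


class _Net:
    def __init__(self, dims: Sequence[int], activation: str, rng: np.random.Generator):
        self.act, self.dact = _ACTIVATIONS[activation]
        self.W = [rng.uniform(-0.5, 0.5, (dims[i], dims[i + 1])) for i in range(len(dims) - 1)]
        self.b = [rng.uniform(-0.5, 0.5, dims[i + 1]) for i in range(len(dims) - 1)]

    def forward(self, X: np.ndarray):
        zs, acts = [], [X]
        a = X
        last = len(self.W) - 1
        # diverged weights propagate NaN/inf silently; divergence is
        # detected and flagged by the caller
        with np.errstate(over="ignore", invalid="ignore"):
            for i, (W, b) in enumerate(zip(self.W, self.b)):
                z = a @ W + b
                a = np.tanh(z) if i == last else self.act(z)
                zs.append(z)
                acts.append(a)
        return zs, acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1][-1].ravel()

    def step(self, X, y, lr, reg, reg_rate):
        # extreme learning rates legitimately overflow; divergence is
        # detected afterwards and flagged, so keep the arithmetic silent
        with np.errstate(over="ignore", invalid="ignore"):
            self._step(X, y, lr, reg, reg_rate)

    def _step(self, X, y, lr, reg, reg_rate):
        zs, acts = self.forward(X)
        out = acts[-1].ravel()
        n = len(y)
        # d(loss)/d(out) for loss = mean((out - y)^2) / 2
        delta = ((out - y) / n)[:, None] * (1.0 - acts[-1] ** 2)
        for i in range(len(self.W) - 1, -1, -1):
            gW = acts[i].T @ delta
            gb = delta.sum(axis=0)
            if reg == "L2":
                gW = gW + reg_rate * self.W[i]
            elif reg == "L1":
                gW = gW + reg_rate * np.sign(self.W[i])
            if i > 0:
                delta = (delta @ self.W[i].T) * self.dact(zs[i - 1], acts[i])
            self.W[i] -= lr * gW
            self.b[i] -= lr * gb


def _loss(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean((pred - y) ** 2) / 2.0)


def _rates(pred: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(TPR, FPR) at the zero decision threshold."""
    called = pred > 0
    pos, neg = y > 0, y <= 0
    tpr = float(called[pos].mean()) if pos.any() else np.nan
    fpr = float(called[neg].mean()) if neg.any() else np.nan
    return tpr, fpr


def train_mlp(
    dataset: pd.DataFrame,
    params: Mapping[str, Any],
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
) -> tuple[list[dict], pd.DataFrame, "_Net"]:
    """Train once up to max(checkpoints); record metrics at each checkpoint.

    Returns (checkpoint records, prediction table at the final epoch, net).
    A non-finite loss flags the remaining checkpoints as failed with missing
    metrics.
    """
    features = [col for name, col in FEATURE_PARAMS.items() if params.get(name, False)]
    if not features:
        raise ValueError("at least one input feature must be enabled")
    checkpoints = sorted(int(c) for c in checkpoints)
    if not checkpoints or checkpoints[0] < 1:
        raise ValueError("checkpoints must be positive epochs")
    X = dataset[features].to_numpy(dtype=float)
    y = dataset["label"].to_numpy(dtype=float)
    rng = np.random.default_rng(int(params.get("seed", 0)))
    n = len(X)
    perm = rng.permutation(n)
    n_train = max(1, min(n - 1, int(round(float(params.get("train_ratio", 0.5)) * n))))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    Xtr, ytr, Xte, yte = X[train_idx], y[train_idx], X[test_idx], y[test_idx]

    n_layers = int(params.get("n_layers", 1))
    dims = [len(features), *([int(params.get("n_neurons", 4))] * n_layers), 1]
    net = _Net(dims, params.get("activation", "tanh"), rng)
    lr = float(params.get("learning_rate", 0.03))
    reg = params.get("regularization", "off")
    reg_rate = float(params.get("regularization_rate", 0.0))
    batch = max(1, int(params.get("batch_size", 10)))

    records: list[dict] = []
    t0 = time.perf_counter()
    epoch = 0
    diverged = False
    for target in checkpoints:
        while epoch < target and not diverged:
            order = rng.permutation(n_train)
            for start in range(0, n_train, batch):
                idx = order[start:start + batch]
                net.step(Xtr[idx], ytr[idx], lr, reg, reg_rate)
            epoch += 1
            if not np.all(np.isfinite(net.W[-1])):
                diverged = True
        elapsed = time.perf_counter() - t0
        rec: dict[str, Any] = {"epoch": target, "status": "ok",
                               "total_time": elapsed, "mean_time": elapsed / max(epoch, 1)}
        tr_pred = net.predict(Xtr)
        te_pred = net.predict(Xte)
        if diverged or not (np.all(np.isfinite(tr_pred)) and np.all(np.isfinite(te_pred))):
            diverged = True
            rec.update(status="failed", train_loss=np.nan, test_loss=np.nan,
                       train_TPR=np.nan, train_FPR=np.nan, test_TPR=np.nan, test_FPR=np.nan)
        else:
            tr_tpr, tr_fpr = _rates(tr_pred, ytr)
            te_tpr, te_fpr = _rates(te_pred, yte)
            rec.update(train_loss=_loss(tr_pred, ytr), test_loss=_loss(te_pred, yte),
                       train_TPR=tr_tpr, train_FPR=tr_fpr, test_TPR=te_tpr, test_FPR=te_fpr)
        records.append(rec)

    pred_all = net.predict(X)
    in_train = np.zeros(n, dtype=bool)
    in_train[train_idx] = True
    predictions = pd.DataFrame(
        {
            "point_id": np.arange(n),
            "true_label": y.astype(int),
            "predicted_label": np.where(pred_all > 0, 1, -1),
            "raw_output": pred_all,
            "split": np.where(in_train, "train", "test"),
        }
    )
    return records, predictions, net


def _decision_figure(dataset: pd.DataFrame, net: "_Net", features: list[str]):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    x1 = dataset["X1"].to_numpy()
    x2 = dataset["X2"].to_numpy()
    g1, g2 = np.meshgrid(
        np.linspace(x1.min() - 0.5, x1.max() + 0.5, 60),
        np.linspace(x2.min() - 0.5, x2.max() + 0.5, 60),
    )
    grid = pd.DataFrame({"X1": g1.ravel(), "X2": g2.ravel()})
    grid["X1^2"] = grid["X1"] ** 2
    grid["X2^2"] = grid["X2"] ** 2
    grid["X1*X2"] = grid["X1"] * grid["X2"]
    grid["sin(X1)"] = np.sin(grid["X1"])
    grid["sin(X2)"] = np.sin(grid["X2"])
    zz = net.predict(grid[features].to_numpy(dtype=float)).reshape(g1.shape)
    ax.contourf(g1, g2, zz, levels=20, cmap="coolwarm", alpha=0.6)
    ax.scatter(x1, x2, c=dataset["label"], cmap="coolwarm", s=8, edgecolors="k",
               linewidths=0.2)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    return fig


def mlp_model_app(input_table: pd.DataFrame, params: Mapping[str, Any]) -> AppResult:
    """One-run contract: train for ``params['epochs']`` epochs and return a
    prediction table, a one-row metrics table and a decision-surface image."""
    epochs = int(params.get("epochs", 50))
    records, predictions, net = train_mlp(input_table, params, checkpoints=[epochs])
    features = [col for name, col in FEATURE_PARAMS.items() if params.get(name, False)]
    return AppResult(
        tables={"predictions": predictions, "metrics": pd.DataFrame([records[-1]])},
        image=_decision_figure(input_table, net, features),
    )


def default_mlp_sweep_spec(seed: int = 0):
    """Sweep spec matching the hyperparameter study: everything sampled over
    its full legal range except the per-run epoch count, which checkpoint
    recording replaces."""
    spec = default_sampling_spec(MLP_MANIFEST, seed=seed)
    spec = spec.set_range("n_layers", 0, 6).set_range("n_neurons", 1, 8)
    for name in FEATURE_PARAMS:
        spec = spec.set_enabled(name, (True, False))
    spec = (
        spec.set_range("train_ratio", 0.1, 0.9)
        .set_range("batch_size", 1, 30)
        .set_range("learning_rate", 0.00001, 10.0)
        .set_enabled("activation", ("linear", "relu", "sigmoid", "tanh"))
        .set_enabled("regularization", ("off", "L1", "L2"))
        .set_range("regularization_rate", 0.0, 1.0)
        .set_range("seed", 0, 1_000_000)
    )
    return spec


def run_mlp_session(
    input_table: pd.DataFrame,
    out_dir: str | Path,
    n_combinations: int,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    seed: int = 0,
    spec=None,
    save_outputs: bool = True,
    save_images: bool = False,
) -> RunsSession:
    """Random hyperparameter sweep with epoch-checkpoint recording.

    Each of the ``n_combinations`` draws trains one network; metrics are
    recorded at every checkpoint epoch, one runsInfo record per checkpoint,
    so the table ends up with ``n_combinations * len(checkpoints)`` rows.
    """
    from ..manifest import validate_sampling_spec

    spec = (spec or default_mlp_sweep_spec()).with_runs(n_combinations, seed=seed)
    validate_sampling_spec(MLP_MANIFEST, spec)
    root = Path(out_dir)
    (root / "runs").mkdir(parents=True, exist_ok=True)
    (root / "images").mkdir(exist_ok=True)
    write_table(input_table, root / INPUT_TABLE)
    param_names = [p.name for p in MLP_MANIFEST.parameters if p.name != "epochs"]
    write_table(
        pd.DataFrame({"name": param_names,
                      "type": [MLP_MANIFEST.parameter(n).kind for n in param_names]}),
        root / PARAM_INFO,
    )
    MLP_MANIFEST.to_json(root / MANIFEST_FILE)
    spec.to_json(root / SPEC_FILE)

    metric_cols = ["epoch", "train_loss", "test_loss", "train_TPR", "train_FPR",
                   "test_TPR", "test_FPR", "total_time", "mean_time"]
    columns = ["run_id", "combination_id", *param_names, *metric_cols, "status"]
    with open(root / RUNS_INFO, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        run_id = 0
        for c in range(n_combinations):
            params = sample_combination(MLP_MANIFEST, spec, c)
            try:
                records, predictions, net = train_mlp(input_table, params, checkpoints)
            except Exception:
                records, predictions = (
                    [{"epoch": e, "status": "failed"} for e in sorted(checkpoints)],
                    None,
                )
            for rec in records:
                if save_outputs and predictions is not None:
                    write_table(predictions, root / "runs" / f"predictions_{run_id}.txt")
                if save_images and predictions is not None:
                    features = [col for name, col in FEATURE_PARAMS.items()
                                if params.get(name, False)]
                    fig = _decision_figure(input_table, net, features)
                    fig.savefig(root / "images" / f"{run_id}.png", dpi=72)
                    import matplotlib.pyplot as plt

                    plt.close(fig)
                row = [str(run_id), str(c),
                       *(format_cell(params[n]) for n in param_names),
                       *(format_cell(rec.get(m, np.nan)) for m in metric_cols),
                       rec.get("status", "ok")]
                fh.write("\t".join(row) + "\n")
                run_id += 1
            fh.flush()
    return load_runs_directory(root)
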