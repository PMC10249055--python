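import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from runsweep import AppResult, default_sampling_spec, parse_manifest, run_session

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


TOY_MANIFEST_DOC = {
    "app_name": "toy",
    "parameters": [
        {"name": "a", "type": "integer", "default": 4, "min": 2, "max": 20},
        {"name": "x", "type": "double", "default": 0.5, "min": 0.0, "max": 1.0},
        {"name": "flag", "type": "boolean", "default": True},
        {"name": "m", "type": "categorical", "default": "x", "items": ["x", "y", "z"]},
        {"name": "note", "type": "string", "default": "hello"},
    ],
    "output_tables": ["TableA", "TableB"],
    "emits_image": False,
}


def toy_app(input_table: pd.DataFrame, params) -> AppResult:
    """Deterministic two-table app used across the derivation tests."""
    a, x = int(params["a"]), float(params["x"])
    n = len(input_table)
    labels = ["x" if (i + a) % 2 == 0 else "y" for i in range(n)]
    table_a = pd.DataFrame({"A1": x * (np.arange(n) + 1.0), "A2": labels})
    table_b = pd.DataFrame({"B1": [a], "B2": [x * 10], "B3": [params["m"]]})
    return AppResult(tables={"TableA": table_a, "TableB": table_b})


@pytest.fixture()
def toy_manifest():
    return parse_manifest(TOY_MANIFEST_DOC)


@pytest.fixture()
def toy_input():
    return pd.DataFrame({"v": np.arange(6.0), "gt": ["TRUE", "FALSE", "NA"] * 2})


@pytest.fixture()
def toy_session(tmp_path, toy_manifest, toy_input):
    """A 8-run toy sweep session on disk."""
    spec = (
        default_sampling_spec(toy_manifest, n_runs=8, seed=11, out_dir=str(tmp_path / "sess"))
        .set_range("a", 2, 19)
        .set_range("x", 0.1, 1.0)
        .set_enabled("m", ("x", "y", "z"))
    )
    return run_session(toy_app, toy_input, toy_manifest, spec)


def make_blobs_table(n_per=20, centers=((0, 0), (8, 8), (0, 8)), scale=0.5, seed=0):
    """Well-separated Gaussian blobs as a clustering input table."""
    rng = np.random.default_rng(seed)
    pts = np.vstack([rng.normal(c, scale, size=(n_per, 2)) for c in centers])
    return pd.DataFrame(pts, columns=["f1", "f2"])
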