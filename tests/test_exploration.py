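"""Filters, histograms, Pareto fronts, quality aggregation, report export."""

import itertools

import numpy as np
import pandas as pd
import pytest

from runsweep import (
    Filter,
    MetricDirectionRegistry,
    ParetoSpec,
    apply_filters,
    export_report,
    histogram,
    normalized_mean_quality,
    pareto_front,
)


@pytest.fixture()
def runs_info():
    rng = np.random.default_rng(0)
    n = 60
    return pd.DataFrame(
        {
            "run_id": np.arange(n),
            "method": rng.choice(["kmeans", "hierarchical", "spectral"], n),
            "k": rng.integers(2, 20, n),
            "score": rng.normal(size=n),
        }
    )


# ---------------------------------------------------------------------------
# filters


def test_categorical_filter_keeps_only_selected_values(runs_info):
    ids = apply_filters(runs_info, [Filter("method", values=("hierarchical",))])
    kept = runs_info[runs_info["run_id"].isin(ids)]
    assert (kept["method"] == "hierarchical").all()
    assert len(kept) == (runs_info["method"] == "hierarchical").sum()


def test_empty_filter_list_keeps_all_runs(runs_info):
    assert apply_filters(runs_info, []).tolist() == runs_info["run_id"].tolist()


def test_filters_match_row_by_row_oracle(runs_info):
    rng = np.random.default_rng(5)
    for _ in range(100):
        lo, hi = sorted(rng.integers(2, 20, 2).tolist())
        methods = tuple(rng.choice(["kmeans", "hierarchical", "spectral"],
                                   rng.integers(1, 3), replace=False))
        filters = [Filter("k", lo=lo, hi=hi), Filter("method", values=methods)]
        ids = set(apply_filters(runs_info, filters))
        oracle = {
            int(row.run_id)
            for row in runs_info.itertuples()
            if lo <= row.k <= hi and row.method in methods
        }
        assert ids == oracle


def test_filters_commute(runs_info):
    filters = [
        Filter("k", lo=3, hi=15),
        Filter("method", values=("kmeans", "spectral")),
        Filter("score", lo=-1.0, hi=2.0),
    ]
    results = {
        tuple(apply_filters(runs_info, list(perm)))
        for perm in itertools.permutations(filters)
    }
    assert len(results) == 1


def test_unknown_filter_column_lists_available(runs_info):
    with pytest.raises(KeyError, match="score"):
        apply_filters(runs_info, [Filter("nope", lo=0, hi=1)])


def test_interval_invariants():
    with pytest.raises(ValueError, match="lo"):
        Filter("k", lo=5, hi=2)
    with pytest.raises(ValueError, match="empty"):
        Filter("k", values=())


# ---------------------------------------------------------------------------
# histograms


def test_categorical_histogram_one_bar_per_value(runs_info):
    summary = histogram(runs_info, "method")
    assert sorted(summary.categories) == ["hierarchical", "kmeans", "spectral"]
    assert summary.total == len(runs_info)


def test_constant_column_single_bin():
    df = pd.DataFrame({"run_id": range(5), "c": [3.0] * 5})
    summary = histogram(df, "c", bins=1)
    assert summary.counts.tolist() == [5]


def test_histogram_counts_match_counting_oracle(runs_info):
    summary = histogram(runs_info, "k", bins=6)
    oracle, _ = np.histogram(runs_info["k"], bins=summary.edges)
    assert summary.counts.tolist() == oracle.tolist()
    assert summary.total == runs_info["k"].notna().sum()


def test_all_missing_column_yields_empty_summary():
    df = pd.DataFrame({"run_id": [0, 1], "m": [np.nan, np.nan]})
    assert histogram(df, "m").total == 0


# ---------------------------------------------------------------------------
# Pareto front


def _oracle_front(df, axes):
    """Plain O(n^2) nested-loop dominance check (the independent oracle)."""
    pts = df[[c for c, _ in axes]].to_numpy(dtype=float)
    signs = np.array([1.0 if d == "maximize" else -1.0 for _, d in axes])
    oriented = pts * signs
    keep = []
    for i in range(len(oriented)):
        dominated = False
        for j in range(len(oriented)):
            if i == j:
                continue
            if all(oriented[j] >= oriented[i]) and any(oriented[j] > oriented[i]):
                dominated = True
                break
        if not dominated:
            keep.append(int(df.iloc[i]["run_id"]))
    return sorted(keep)


def test_single_point_is_its_own_front():
    df = pd.DataFrame({"run_id": [7], "fpr": [0.3], "tpr": [0.6]})
    spec = ParetoSpec((("fpr", "minimize"), ("tpr", "maximize")))
    assert pareto_front(df, spec).tolist() == [7]


def test_roc_corner_dominates():
    # (0,1) dominates both (1,0) and (1,1) under minimize-FPR / maximize-TPR
    df = pd.DataFrame({"run_id": [0, 1, 2], "fpr": [0, 1, 1], "tpr": [1, 0, 1]})
    spec = ParetoSpec((("fpr", "minimize"), ("tpr", "maximize")))
    assert pareto_front(df, spec).tolist() == [0]


def test_duplicated_frontier_points_all_returned():
    df = pd.DataFrame({"run_id": [0, 1, 2], "fpr": [0.1, 0.1, 0.5], "tpr": [0.9, 0.9, 0.2]})
    spec = ParetoSpec((("fpr", "minimize"), ("tpr", "maximize")))
    assert pareto_front(df, spec).tolist() == [0, 1]


def test_front_matches_oracle_on_500_random_points():
    rng = np.random.default_rng(12)
    df = pd.DataFrame(
        {"run_id": np.arange(500), "fpr": rng.random(500), "tpr": rng.random(500)}
    )
    spec = ParetoSpec((("fpr", "minimize"), ("tpr", "maximize")))
    assert pareto_front(df, spec).tolist() == _oracle_front(df, spec.axes)


def test_front_is_idempotent_and_every_loser_has_a_witness():
    rng = np.random.default_rng(3)
    df = pd.DataFrame(
        {"run_id": np.arange(200), "a": rng.random(200), "b": rng.random(200)}
    )
    spec = ParetoSpec((("a", "minimize"), ("b", "maximize")))
    front = pareto_front(df, spec)
    sub = df[df["run_id"].isin(front)]
    assert pareto_front(sub, spec).tolist() == front.tolist()
    front_pts = sub[["a", "b"]].to_numpy()
    losers = df[~df["run_id"].isin(front)][["a", "b"]].to_numpy()
    for a, b in losers:
        assert any((fa <= a and fb >= b) and (fa < a or fb > b) for fa, fb in front_pts)


def test_pareto_spec_needs_two_axes():
    with pytest.raises(ValueError, match="2 axes"):
        ParetoSpec((("a", "minimize"),))


# ---------------------------------------------------------------------------
# normalized mean quality


def test_hand_computed_three_run_aggregate():
    df = pd.DataFrame(
        {
            "run_id": [0, 1, 2],
            "calinski_harabasz": [10.0, 20.0, 30.0],   # higher better -> 0, .5, 1
            "davies_bouldin": [0.2, 0.6, 1.0],          # lower better -> 1, .5, 0
        }
    )
    agg = normalized_mean_quality(df, ["calinski_harabasz", "davies_bouldin"])
    assert agg.tolist() == pytest.approx([0.5, 0.5, 0.5])
    # and with only the higher-is-better metric the ranking is preserved
    agg2 = normalized_mean_quality(df, ["calinski_harabasz"])
    assert agg2.tolist() == pytest.approx([0.0, 0.5, 1.0])


def test_constant_metrics_map_to_half():
    df = pd.DataFrame({"run_id": [0, 1], "silhouette": [0.4, 0.4], "gap": [1.0, 1.0]})
    agg = normalized_mean_quality(df, ["silhouette", "gap"])
    assert agg.tolist() == pytest.approx([0.5, 0.5])


def test_aggregate_invariant_under_positive_affine_rescaling():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(
        {
            "run_id": np.arange(20),
            "calinski_harabasz": rng.random(20) * 100,
            "s_dbw": rng.random(20),
        }
    )
    base = normalized_mean_quality(df, ["calinski_harabasz", "s_dbw"])
    scaled = df.copy()
    scaled["calinski_harabasz"] = 3.7 * scaled["calinski_harabasz"] + 11.0
    scaled["s_dbw"] = 0.02 * scaled["s_dbw"] + 5.0
    again = normalized_mean_quality(scaled, ["calinski_harabasz", "s_dbw"])
    np.testing.assert_allclose(base.to_numpy(), again.to_numpy(), atol=1e-12)


def test_unregistered_metric_requires_direction():
    df = pd.DataFrame({"run_id": [0], "mystery": [1.0]})
    with pytest.raises(KeyError, match="mystery"):
        normalized_mean_quality(df, ["mystery"])
    registry = MetricDirectionRegistry()
    registry.register("mystery", higher_is_better=False)
    normalized_mean_quality(df, ["mystery"], registry)  # now fine


# ---------------------------------------------------------------------------
# report export


def test_report_row_counts_match_filters(toy_session, tmp_path):
    config = {
        "filters": [{"column": "a", "lo": 2, "hi": 10}],
        "scatter": [{"x": "a", "y": "x", "color": "m"}],
        "histograms": ["a", "m"],
    }
    out = export_report(toy_session, config, tmp_path / "report")
    table = pd.read_csv(out / "runs_filtered.tsv", sep="\t")
    expected = toy_session.runs_info.query("2 <= a <= 10")
    assert len(table) == len(expected)
    assert (out / "index.html").exists()
    assert (out / "hist_a.png").exists()


def test_report_on_empty_filter_result_is_valid(toy_session, tmp_path):
    config = {"filters": [{"column": "a", "lo": 100, "hi": 200}],
              "histograms": ["a"], "scatter": [{"x": "a", "y": "x"}]}
    out = export_report(toy_session, config, tmp_path / "empty")
    assert (out / "index.html").exists()
    assert len(pd.read_csv(out / "runs_filtered.tsv", sep="\t")) == 0


def test_report_pareto_table(tmp_path, toy_session):
    from runsweep import DerivationPass, apply_passes

    apply_passes(toy_session, [DerivationPass("mean", table="TableA", column="A1")])
    config = {"pareto": {"axes": [["mean_A1", "maximize"], ["x", "minimize"]]}}
    out = export_report(toy_session, config, tmp_path / "rep")
    front = pd.read_csv(out / "pareto_front.tsv", sep="\t")
    assert len(front) >= 1
    assert set(front["run_id"]).issubset(set(toy_session.runs_info["run_id"]))
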