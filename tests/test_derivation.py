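"""Derivation passes: naming templates, conservation laws, oracles."""

import numpy as np
import pandas as pd
import pytest

from runsweep import (
    DerivationError,
    DerivationPass,
    apply_passes,
    derive_aggregate,
    derive_class_label_stats,
    derive_dimred,
    derive_gt_comparison,
    derive_take_first_row,
    load_runs_directory,
)


def make_external_session(tmp_path, tables_by_run, input_table=None, table_name="T"):
    """Write a minimal runs directory by hand: one output table per run."""
    root = tmp_path / "ext"
    (root / "runs").mkdir(parents=True)
    with open(root / "runsInfo.txt", "w") as fh:
        fh.write("run_id\tp\n")
        for i in range(len(tables_by_run)):
            fh.write(f"{i}\t{i * 0.1}\n")
    for i, df in enumerate(tables_by_run):
        if df is not None:
            df.to_csv(root / "runs" / f"{table_name}_{i}.txt", sep="\t",
                      index=False, na_rep="NA")
    if input_table is not None:
        input_table.to_csv(root / "input.txt", sep="\t", index=False, na_rep="NA")
    return load_runs_directory(root)


# ---------------------------------------------------------------------------
# aggregates


def test_aggregate_naming_and_values(toy_session):
    derived = derive_aggregate(toy_session, "TableA", "A1", "mean")
    assert derived.labels == ["mean_A1"]
    for pos, run_id in enumerate(toy_session.runs_info["run_id"]):
        expected = toy_session.output_table("TableA", int(run_id))["A1"].mean()
        assert derived.values.iloc[pos, 0] == pytest.approx(expected)


def test_single_row_table_all_aggregates_equal_the_value(tmp_path):
    session = make_external_session(tmp_path, [pd.DataFrame({"A1": [7.5]})], table_name="TableA")
    for fn in ("mean", "sum", "median", "min", "max"):
        derived = derive_aggregate(session, "TableA", "A1", fn)
        assert derived.values.iloc[0, 0] == 7.5


def test_median_matches_sort_and_pick_oracle(tmp_path):
    rng = np.random.default_rng(3)
    tables = [pd.DataFrame({"A1": rng.normal(size=7)}) for _ in range(20)]
    session = make_external_session(tmp_path, tables, table_name="TableA")
    derived = derive_aggregate(session, "TableA", "A1", "median")
    for i, t in enumerate(tables):
        oracle = sorted(t["A1"])[3]  # middle of 7
        assert derived.values.iloc[i, 0] == pytest.approx(oracle, rel=1e-12)


def test_aggregate_on_non_numeric_column_names_run(toy_session):
    with pytest.raises(DerivationError, match="not numeric"):
        derive_aggregate(toy_session, "TableA", "A2", "mean")


def test_missing_run_table_yields_missing_value(tmp_path):
    tables = [pd.DataFrame({"A1": [1.0]}), None, pd.DataFrame({"A1": [3.0]})]
    session = make_external_session(tmp_path, tables, table_name="TableA")
    derived = derive_aggregate(session, "TableA", "A1", "mean")
    assert np.isnan(derived.values.iloc[1, 0])
    assert derived.values.iloc[2, 0] == 3.0


# ---------------------------------------------------------------------------
# class-label statistics


def test_count_per_class_label_names_and_zero_fill(tmp_path):
    tables = [pd.DataFrame({"A2": ["x", "x", "y"]}), pd.DataFrame({"A2": ["x", "x", "x"]})]
    session = make_external_session(tmp_path, tables, table_name="TableA")
    derived = derive_class_label_stats(session, "TableA", "A2", "count_per_class_label")
    assert derived.labels == ["n(A2 = x)", "n(A2 = y)"]
    assert derived.values.iloc[0].tolist() == [2, 1]
    assert derived.values.iloc[1].tolist() == [3, 0]  # zero-filled, stays rectangular
    # per-run counts sum to the run's row count
    assert (derived.values.sum(axis=1) == 3).all()


def test_n_class_labels_column_is_named_after_the_table(tmp_path):
    tables = [pd.DataFrame({"cluster_id": [0, 1, 1, 2]}), pd.DataFrame({"cluster_id": [0, 0, 0, 0]})]
    session = make_external_session(tmp_path, tables, table_name="cluster_ids")
    derived = derive_class_label_stats(session, "cluster_ids", "cluster_id", "n_class_labels")
    assert derived.labels == ["Num(cluster_ids)"]
    assert derived.values["Num(cluster_ids)"].tolist() == [3, 1]


def test_mode_and_degenerate_single_label(tmp_path):
    tables = [pd.DataFrame({"A2": ["q"] * 5})]
    session = make_external_session(tmp_path, tables, table_name="TableA")
    n = derive_class_label_stats(session, "TableA", "A2", "n_class_labels")
    mode = derive_class_label_stats(session, "TableA", "A2", "mode_class_labels")
    assert n.values.iloc[0, 0] == 1
    assert mode.labels == ["mode_A2"] and mode.values.iloc[0, 0] == "q"


# ---------------------------------------------------------------------------
# ground-truth comparison


def _gt_fixture(tmp_path, n_rows=200, n_runs=6, seed=0):
    rng = np.random.default_rng(seed)
    truth = rng.choice(["TRUE", "FALSE", "NA"], size=n_rows, p=[0.2, 0.1, 0.7])
    input_table = pd.DataFrame({"GT_DE": truth})
    tables = [
        pd.DataFrame({"isDE": rng.choice(["TRUE", "FALSE"], size=n_rows)})
        for _ in range(n_runs)
    ]
    session = make_external_session(tmp_path, tables, input_table=input_table,
                                    table_name="de_results")
    return session, truth, tables


def test_gt_comparison_emits_six_paper_named_columns(tmp_path):
    session, truth, tables = _gt_fixture(tmp_path)
    derived = derive_gt_comparison(session, "de_results", "isDE", "GT_DE")
    assert "n(isDE = TRUE & GT_DE = TRUE)" in derived.labels
    assert len(derived.labels) == 6
    # conservation: the six counts sum to the row count, for every run
    assert (derived.values.sum(axis=1) == len(truth)).all()


def test_gt_comparison_matches_nested_loop_crosstab(tmp_path):
    session, truth, tables = _gt_fixture(tmp_path, seed=42)
    derived = derive_gt_comparison(session, "de_results", "isDE", "GT_DE")
    for i, t in enumerate(tables):
        for p in ("TRUE", "FALSE"):
            for g in ("TRUE", "FALSE", "NA"):
                oracle = sum(
                    1 for pv, gv in zip(t["isDE"], truth) if pv == p and gv == g
                )
                assert derived.values.iloc[i][f"n(isDE = {p} & GT_DE = {g})"] == oracle


def test_gt_comparison_single_cell_mass(tmp_path):
    input_table = pd.DataFrame({"gt": ["NA"] * 10})
    tables = [pd.DataFrame({"pred": ["FALSE"] * 10})]
    session = make_external_session(tmp_path, tables, input_table=input_table, table_name="T")
    derived = derive_gt_comparison(session, "T", "pred", "gt")
    v = derived.values.iloc[0]
    assert v["n(pred = FALSE & gt = NA)"] == 10
    assert v.drop("n(pred = FALSE & gt = NA)").sum() == 0


def test_gt_comparison_row_count_mismatch_is_fatal(tmp_path):
    input_table = pd.DataFrame({"gt": ["NA"] * 5})
    tables = [pd.DataFrame({"pred": ["TRUE"] * 4})]
    session = make_external_session(tmp_path, tables, input_table=input_table, table_name="T")
    with pytest.raises(DerivationError, match="rows"):
        derive_gt_comparison(session, "T", "pred", "gt")


# ---------------------------------------------------------------------------
# dimensionality reduction over runs


def test_dimred_shape_contract_and_duplicate_symmetry(tmp_path):
    rng = np.random.default_rng(1)
    base = pd.DataFrame({"v": rng.normal(size=5)})
    tables = [base.copy(), base.copy()] + [
        pd.DataFrame({"v": rng.normal(size=5)}) for _ in range(8)
    ]
    session = make_external_session(tmp_path, tables, table_name="out")
    for method in ("pca", "mds"):
        derived = derive_dimred(session, "out", None, method)
        assert derived.labels == [f"{method}1(out)", f"{method}2(out)"]
        assert len(derived.values) == 10
        # duplicate runs land on identical coordinates
        np.testing.assert_allclose(
            derived.values.iloc[0].to_numpy(dtype=float),
            derived.values.iloc[1].to_numpy(dtype=float),
            atol=1e-9,
        )


def test_dimred_pca_recovers_rank_two_geometry(tmp_path):
    rng = np.random.default_rng(7)
    latent = rng.normal(size=(12, 2))
    mix = rng.normal(size=(2, 6))
    tables = [pd.DataFrame({"v": latent[i] @ mix}) for i in range(12)]
    session = make_external_session(tmp_path, tables, table_name="out")
    derived = derive_dimred(session, "out", None, "pca")
    coords = derived.values.to_numpy(dtype=float)
    from scipy.spatial.distance import pdist

    d_true = pdist(latent @ mix)
    d_emb = pdist(coords)
    # rank-2 data: the 2-D embedding preserves all pairwise distances
    np.testing.assert_allclose(d_emb, d_true, atol=1e-8)


def test_dimred_needs_two_complete_runs(tmp_path):
    session = make_external_session(tmp_path, [pd.DataFrame({"v": [1.0, 2.0]}), None],
                                    table_name="out")
    with pytest.raises(DerivationError, match="at least 2"):
        derive_dimred(session, "out", None, "pca")


def test_dimred_unequal_lengths_fatal(tmp_path):
    tables = [pd.DataFrame({"v": [1.0, 2.0]}), pd.DataFrame({"v": [1.0, 2.0, 3.0]})]
    session = make_external_session(tmp_path, tables, table_name="out")
    with pytest.raises(DerivationError, match="length"):
        derive_dimred(session, "out", None, "pca")


# ---------------------------------------------------------------------------
# take_first_row and pass orchestration


def test_take_first_row_adopts_table_columns(toy_session):
    derived = derive_take_first_row(toy_session, "TableB")
    assert derived.labels == ["B1", "B2", "B3"]


def test_three_pass_sequence_appends_expected_column_count(toy_session):
    before = list(toy_session.runs_info.columns)
    info = apply_passes(
        toy_session,
        [
            DerivationPass("mean", table="TableA", column="A1"),
            DerivationPass("count_per_class_label", table="TableA", column="A2"),
            DerivationPass("take_first_row", table="TableB"),
        ],
    )
    added = [c for c in info.columns if c not in before]
    # 1 aggregate + 2 label counts + 3 first-row columns
    assert added == ["mean_A1", "n(A2 = x)", "n(A2 = y)", "B1", "B2", "B3"]


def test_none_pass_changes_nothing(toy_session):
    before = toy_session.runs_info.copy()
    info = apply_passes(toy_session, [DerivationPass("none")])
    pd.testing.assert_frame_equal(info, before)


def test_apply_passes_is_idempotent_and_persists(toy_session):
    passes = [
        DerivationPass("mean", table="TableA", column="A1"),
        DerivationPass("take_first_row", table="TableB"),
    ]
    once = apply_passes(toy_session, passes).copy()
    twice = apply_passes(toy_session, passes)
    pd.testing.assert_frame_equal(once, twice)
    reloaded = load_runs_directory(toy_session.root)
    pd.testing.assert_frame_equal(reloaded.runs_info, twice)


def test_derived_column_may_not_collide_with_parameters(toy_session):
    # a first-row table whose columns shadow the parameter column "a"
    bad = pd.DataFrame({"a": [1]})
    for run_id in toy_session.runs_info["run_id"]:
        bad.to_csv(toy_session.root / "runs" / f"Bad_{run_id}.txt", sep="\t", index=False)
    with pytest.raises(DerivationError, match="collide"):
        apply_passes(toy_session, [DerivationPass("take_first_row", table="Bad")])


def test_derivation_never_mutates_run_files(toy_session):
    paths = sorted((toy_session.root / "runs").iterdir())
    before = [(p.name, p.read_bytes()) for p in paths]
    apply_passes(toy_session, [DerivationPass("mean", table="TableA", column="A1")])
    after = [(p.name, p.read_bytes()) for p in sorted((toy_session.root / "runs").iterdir())]
    assert before == after
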