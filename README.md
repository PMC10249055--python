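# runsweep

Headless parameter-space exploration for computer models.

Many scientific models — clustering algorithms, differential-expression
callers, neural-network trainers — expose a handful of control parameters,
and the honest way to understand them is to run the model many times over
random parameter combinations and study the results as a table. `runsweep`
implements that workflow end to end:

1. **Declare** a model's parameters once in a small JSON manifest
   (name, type, default, bounds or items per parameter).
2. **Sample** random parameter combinations uniformly within user-chosen
   sub-ranges, execute the model per combination, and persist everything in
   a flat, tool-agnostic *runs directory* (`runsInfo.txt` with one row per
   run, plus per-run output tables and images). Sessions can be stopped and
   resumed without corrupting or changing the combination stream.
3. **Derive** per-run summaries from the raw outputs — aggregates, class-
   label statistics, confusion counts against a ground-truth column,
   2-D embeddings of whole runs, or a model's own self-reported metrics —
   appended as named columns to the runs table.
4. **Explore** the table headlessly: composable filters, histograms,
   direction-aware quality aggregation, Pareto-frontier extraction, and a
   static plot/table report.

Three bundled demo apps, each with a seeded synthetic-data generator,
reproduce classic use cases offline: cluster-validity analysis over a
binary feature table (403 paintings x 67 motifs), ROC benchmarking of a
differential-expression caller on a spike-in count table with known truth
(21,716 genes, 92 spike-ins), and hyperparameter sweeps of a small MLP over
2-D toy datasets (gauss / circle / xor / spiral).

## The core objects

A *run* is one model execution with a concrete parameter combination,
identified by an integer id. The sweep writes

```
out_dir/
  input.txt        # the model's input table (TSV)
  paramInfo.txt    # parameter name/type table
  runsInfo.txt     # one row per run: run_id, parameter values, status
  runs/            # TableA_0.txt, TableB_0.txt, TableA_1.txt, ...
  images/          # 0.png, 1.png, ...
```

Derivation passes append columns with predictable names: applying `mean`
to column `A1` yields `mean_A1`; counting labels of `A2` yields
`n(A2 = x)`, `n(A2 = y)`; comparing a boolean prediction `isDE` with a
ternary truth `GT_DE` yields the six confusion columns
`n(isDE = TRUE & GT_DE = TRUE)` (true positives) through
`n(isDE = FALSE & GT_DE = NA)`. For optimization axes
(x₁, d₁), …, (xₖ, dₖ) the *Pareto frontier* is the set of runs not weakly
dominated on all axes with strict improvement on one — e.g. minimize false
positives while maximizing true positives in an ROC analysis.

## Worked example

Sweep the differential-expression demo and extract the ROC frontier:

```bash
python examples/de_benchmark_roc.py
```

which prints (abridged):

```
 run_id p_adjust  fdr_threshold  cpm_cutoff  n(isDE = TRUE & GT_DE = FALSE)  n(isDE = TRUE & GT_DE = TRUE)
     46     holm       0.987377    5.451077                             0.0                           58.0
     45       BH       0.282164    3.956708                             1.0                           65.0
     47       BH       0.672694    6.355074                             3.0                           67.0
     30     none       0.825070    3.753829                            17.0                           69.0

8 of 60 parameter combinations are Pareto-optimal.
```

Each row is one caller configuration; the two count columns are false
positives (out of 23 ground-truth-negative spike-ins) and true positives
(out of 69 ground-truth-positive spike-ins). Stringent settings sit in the
lower-left of the ROC plane, sensitive ones upper-right; the frontier rows
are those no other configuration beats on both axes at once. A false-positive
count of 1 corresponds to an FPR of 1/23 ≈ 4%.

The same pipeline is available from the shell:

```bash
runsweep fixtures seqc --out counts.tsv --genes 2000 --seed 0
runsweep sample --app de_caller --input counts.tsv --runs 60 --out session/ --seed 11
runsweep derive --dir session/ --plan plan.json      # e.g. the gt_comparison pass
runsweep report --dir session/ --report-config roc.json --out report/
```

`examples/clustering_sweep.py` (validity-index ranking of clusterings) and
`examples/mlp_hyperparameter_sweep.py` (epoch-checkpointed hyperparameter
sweep) walk through the other two bundled workflows.

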