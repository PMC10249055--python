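# Methods

This note documents the models, conventions and numerical choices behind
`runsweep`: the sweep machinery itself, the derivation semantics, the
exploration analytics, and the three bundled demo workflows with their
synthetic-data generators.

## Parameter sampling

Only uniform random sampling is implemented. For a directive with a numeric
range, integers are drawn uniformly on the **closed** interval [lo, hi]
(both endpoints included) and doubles uniformly on [lo, hi); boolean and
categorical parameters are drawn uniformly over their enabled sets; all
other kinds (string, filename, output) stay constant. A singleton enabled
set behaves exactly as a constant.

Randomness is *counter-based*: draw `i` of a sweep with seed `s` uses an
independent generator keyed by `SeedSequence(entropy=s, spawn_key=(i,))`.
Consequences worth relying on:

* two sessions with equal (manifest, spec, seed) produce identical
  parameter columns;
* a session interrupted after m runs and resumed later reproduces the
  combination stream of an uninterrupted session — resume appends run IDs
  continuing from the maximum existing ID and draws the exact combinations
  the original session would have drawn;
* runsInfo.txt is appended row-by-row with flushing, so an interrupt
  leaves a loadable prefix rather than a corrupt file.

A `status` column records app failures per run (the sweep continues), and
`duration_seconds` records wall time per run. Parameter dependency
declarations are parsed and kept for documentation but never enforced
during sampling.

Wall-clock-bounded sampling is deliberately absent: run counts compose and
reproduce; end-time budgets do not.

## Derivation semantics

Each pass maps one output table per run to one or more scalar/categorical
values, appended to runsInfo under fixed name templates (`mean_A1`,
`Num(<table>)`, `mode_<column>`, `n(<column> = <label>)`,
`n(<pred> = <P> & <gt> = <G>)`, `<method>1(<table>)`/`<method>2(<table>)`,
or — for `take_first_row` — the table's own column names). Conventions:

* missing or unreadable run outputs yield NA values, never silent zeros;
* `count_per_class_label` uses the union of labels over all runs as its
  column universe, zero-filled per run, so runsInfo stays rectangular;
* the ground-truth comparison is the binary-prediction x ternary-truth
  case (prediction in {TRUE, FALSE}, truth in {TRUE, FALSE, NA}); its six
  counts always sum to the compared table's row count. Multi-class
  comparison is an extension point, not implemented;
* re-running a pass replaces its columns (derivation plans are
  idempotent); parameter and bookkeeping columns can never be overwritten;
* runsInfo.txt is rewritten atomically (write-temp-then-rename); raw run
  files are never modified by derivation.

Run-level dimensionality reduction flattens each run's selected numeric
columns into one feature vector and embeds the runs-x-features matrix into
2-D. PCA and t-SNE come from scikit-learn (t-SNE seeded, perplexity
min(30, (n_runs−1)/3)); MDS is classical Torgerson scaling computed in
closed form from the double-centered squared-distance matrix, which makes
it deterministic, exact on genuinely low-rank data, and guarantees that
duplicate runs land on identical coordinates. Signs of MDS axes are fixed
by making the largest-magnitude loading positive.

## Exploration analytics

Filters are conjunctions of per-column predicates (closed numeric interval
or categorical subset) and therefore commute; missing values never match a
numeric interval. Histograms use Sturges' rule for numeric columns unless
a bin count is given. Pareto dominance is weak dominance with strict
improvement on at least one axis; exact ties on all axes keep every tied
run on the frontier. ROC-style analyses are done on raw confusion *counts*
with plot axis maxima set to the known class totals (for the bundled
benchmark: 23 ground-truth-negative and 69 ground-truth-positive
spike-ins), rather than converting to rates during derivation.

The `mean normalized` quality aggregate min-max normalizes each metric to
[0, 1] over its non-missing runs, inverts metrics registered as
lower-is-better, and averages per run over available metrics. The default
direction registry orients the five clustering indices (higher is better:
Calinski–Harabasz, Silhouette, Gap; lower is better: Davies–Bouldin,
S_Dbw) and is overridable per call. A constant metric column carries no
ranking information and maps to 0.5 with a warning; the aggregate is
invariant under positive affine rescaling of any input metric.

Report export is the headless stand-in for an interactive workspace:
PNG scatter plots (optional categorical coloring and render-time-only
seeded jitter), per-column histograms, the filtered runs table, the
Pareto-front table, and copies of selected runs' images behind a plain
HTML index.

## Clustering demo

The clustering app exposes k-means (lloyd/elkan), spectral clustering
(rbf / nearest-neighbor affinity), hierarchical clustering with six
linkage rules (ward, complete, average, single, median, centroid; the
latter two via scipy, which implements them on raw observations) and
DBSCAN (eps, min_samples). Labels are always relabeled to consecutive
non-negative integers; methods may legitimately return fewer clusters than
requested, which the `Num(cluster_ids)` derivation exposes. Degenerate
input (all rows identical) collapses to a single cluster with a warning.

Per run the app emits a one-row `quality_criteria` table with five
validity indices. Calinski–Harabasz, mean Silhouette and Davies–Bouldin
are scikit-learn's implementations; conventions: indices requiring at
least two clusters are NA for single-cluster labelings, CH/DB/Silhouette
are additionally NA when every cluster is a singleton (k = n), and a
singleton cluster inside a larger labeling contributes silhouette 0.
The Gap statistic follows Tibshirani's construction: Gap =
mean_b log(W*_b) − log(W), with W the within-cluster dispersion of the
observed labeling and each W*_b obtained by k-means (same cluster count,
single init) on a reference dataset drawn uniformly over the per-feature
bounding box; B defaults to 10 and is exposed as the `gap_references`
parameter (small B = "fast index settings" for large sweeps). S_Dbw is
implemented from its original definition: average relative cluster
scattering plus inter-cluster density, where densities count points within
a radius equal to the average cluster-variance norm; a zero denominator in
the density ratio contributes 0.

The paintings-like generator emits a 403 x 67 binary table with four
planted scene types (seascape, mountain, river, winter), each switching on
a 6-feature co-occurrence block (within-type firing probability 0.85,
outside 0.06), three near-universal features at 0.8 and filler motifs at
0.15. This guarantees real cluster structure: within-block feature columns
have much higher pairwise Jaccard similarity than across blocks. It is a
structural stand-in, not a fit to any real catalogue.

## Spike-in differential-expression demo

The generator emulates a two-condition, five-replicate bulk RNA-seq
benchmark with a spike-in panel of known truth. Gene-wise base means are
log-normal (meanlog = log 80, sdlog = 1.5); dispersions are
gamma(shape 2, scale 0.01) + 10⁻³ — deliberately low, as spike-in
benchmarks are technical-replicate designs; counts are negative binomial
with variance μ + αμ². Of 92 spike-in rows, 23 have ratio 1 between
conditions (GT_DE = FALSE) and 69 split 23/23/23 over ratios
{0.5, 0.67, 2} (GT_DE = TRUE); condition-B spike-in means equal
ratio x condition-A means. All other genes carry GT_DE = NA; by default 5%
of them are truly DE with log2 fold changes ~ N(0, 1), so the
unknown-truth bulk behaves like real data rather than a pure null. Counts
are not claimed to match any particular real dataset's depth or
mean-dispersion relationship.

The demo caller is a transparent two-group test whose *parameters* mirror
the knobs practitioners sweep in real DE packages. Pipeline: library-size
normalization (total-count or DESeq-style median-of-ratios); genes below
the CPM cutoff in **all** samples are excluded from testing (DE = 0);
tested genes are scored by the difference of mean log normalized counts
(+0.5 pseudocount) between conditions over its standard error. The
log-scale variance follows the negative-binomial delta approximation
var(log x) ≈ α + 1/μ. In `per_gene` mode it is estimated by the pooled
per-gene sample variance and shrunk by empirical-Bayes moderation (a
scaled inverse-chi-square prior fitted by the moments of log s², Smyth's
construction), with the statistic referred to Student t on
residual + prior degrees of freedom; in `common` mode the dispersion
component is replaced by its across-gene median and the statistic referred
to the normal, as common-dispersion count models do. P-values are adjusted
by Benjamini–Hochberg, Holm, Bonferroni or left raw (statsmodels), and
DE = sign(log-ratio) where the adjusted p falls below the FDR threshold.

The moderated pooled-variance construction is what keeps the caller
honest at n = 5 + 5: the pooled variance estimator is chi-square with
8 df and independent of the numerator, so the t reference is near-exact,
and moderation recovers the power that per-gene variance noise otherwise
costs. Welch–Satterthwaite, by contrast, is measurably conservative at
equal small n, and a plain normal reference is anti-conservative. The test
suite verifies type-I calibration directly: under the global null
(no spike-ins, no nuisance DE, 2,000 genes), the mean fraction of genes
called at unadjusted p < 0.05 over 50 seeded datasets must lie within
3 standard errors of 0.05.

## MLP demo

The playground generator emits 200 points split exactly 100/100 between
labels −1/+1 for four shapes (two Gaussian blobs, concentric circles, an
XOR quadrant layout, two interleaved Archimedean spiral arms with angle
proportional to radius and labels by arm), plus the seven standard feature
transforms (X1, X2, X1², X2², X1·X2, sin X1, sin X2). The noise dial in
[0, 50] widens the Gaussian blobs from sd 0.5 to 2.0 and adds uniform
coordinate jitter elsewhere (amplitude 5·noise/100 for circle/xor,
noise/100 for the tightly wound spiral); labels come from the clean
geometry, so jitter produces genuine label noise near boundaries. The
exact constants are this package's own, fixed here.

The classifier is a fully connected net with 0–6 hidden layers of 1–8
neurons, hidden activation in {linear, relu, sigmoid, tanh} (linear is the
identity f(x) = x, so any depth collapses to an affine map), a tanh output
neuron, and loss = mean((out − y)²)/2 on ±1 targets (a constant-zero
predictor scores 0.5, a perfect one 0; the recorded loss excludes the
regularization penalty). Training is mini-batch gradient descent with
per-epoch reshuffling, optional L1/L2 penalties, and uniform(−0.5, 0.5)
seeded weight initialization; with learning rate 0 training is exactly a
no-op. Divergence (non-finite weights or predictions) flags the run failed
with missing metrics. At each requested epoch checkpoint the trainer
records train/test loss, TPR and FPR at the zero threshold, total and
mean per-epoch time; the sweep driver writes one runsInfo record per
(combination, checkpoint) — `epoch` is an ordinary recorded column — which
is also the package's reference example of an externally-produced runs
directory whose derived columns arrive pre-computed (derivation method
"none").

## What the synthetic data does and does not show

The generators reproduce the *structure* of the three case studies — table
shapes, spike-in census, class balance, ground-truth encoding — and enough
signal (planted blocks, known ratios, separable-to-hard geometries) for
the analysis machinery to produce meaningful rankings, ROC frontiers and
convergence contrasts. Passing tests therefore demonstrate that the sweep,
derivation and exploration semantics are correct, and that the demo models
behave qualitatively as their real counterparts do. They do not reproduce
findings that depend on real data or the original tools: the Pareto
structure of any particular production DE package's parameter space, its
up/down-regulation biases, or exact convergence percentages of the
original web-based network trainer. Where a property test needs a
regime choice, it uses the clean-geometry limit (noise 0) so the
linear-inseparability arguments are exact; the spiral contrast uses two
hidden layers, since one marginal 8-neuron layer on raw coordinates sits
at the edge of representability.

## Desk-scale defaults used by the shipped checks

The structural session checks run at reduced size by design: the 1,000-run
clustering sweep uses a 60-point blob table with `gap_references=2` and
PCA run images; the 500-run DE sweep uses a 2,000-gene benchmark; the
2,500-combination MLP sweep records checkpoints {2, 4, 6, 8} with per-run
prediction tables disabled (the record count, not the training quality, is
what those checks assert). The full-size generators (21,716 genes;
403 x 67 table) are exercised where the claim is about the data itself.

## Known limitations

* Uniform sampling only; no grid, stratified or adaptive designs, and no
  surrogate modeling of unsampled combinations.
* The manifest dialect is JSON; generating manifests from annotated source
  code of another language is out of scope.
* The ground-truth derivation handles boolean predictions only.
* The DE caller is a demonstration model: it ignores count outliers,
  assumes equal within-group variances on the log scale, and its `common`
  dispersion mode trades calibration for simplicity.
* Executing external command-line models is not wired in; external tools
  can instead write the documented directory layout and be analyzed with
  `load_runs_directory` (the MLP sweep driver shows the pattern).
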