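"""Spike-in differential-expression benchmark: generator and demo caller.

The generator emulates a bulk RNA-seq benchmark experiment: two biological
conditions with five replicates each, negative-binomial counts, and a panel
of 92 spike-in genes added in known amounts so their true differential-
expression (DE) state is known a priori. 23 spike-ins have an identical
ratio between conditions (ground-truth non-DE); the remaining 69 have
ratios 0.5, 0.67 or 2 (ground-truth DE, 23 each). All other genes carry
GT_DE = NA. The full table has 21,716 gene rows and 10 count columns.

The demo DE caller is a deliberately simple, fully offline two-group test
whose *parameters* mirror the knobs a practitioner would sweep in a real
DE package: normalization strategy, dispersion handling, a CPM expression
floor, the multiple-testing correction and the FDR threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Any, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ..manifest import AppManifest, ParameterSpec
from ..sampler import AppResult

logger = logging.getLogger(__name__)

__all__ = [
    "SEQCLikeConfig",
    "generate_seqc_like",
    "DE_CALLER_MANIFEST",
    "de_caller_app",
]


@dataclass(frozen=True)
class SEQCLikeConfig:
    """Study conditions for the synthetic benchmark.

    ``n_genes`` is the total row count including spike-ins. Gene-wise base
    means are log-normal, dispersions gamma-distributed; a small fraction of
    background genes is truly DE (nuisance DE) so the unknown-truth portion
    behaves like real data rather than a pure null.
    """

    n_genes: int = 21_716
    n_spikein: int = 92
    n_null_spikein: int = 23
    spike_ratios: tuple[float, ...] = (0.5, 0.67, 2.0)
    n_replicates: int = 5
    mean_log_mu: float = float(np.log(80.0))
    mean_log_sigma: float = 1.5
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.01
    nuisance_de_fraction: float = 0.05
    nuisance_lfc_sigma: float = 1.0

    @property
    def n_de_spikein(self) -> int:
        return self.n_spikein - self.n_null_spikein


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and variance mean + alpha*mean^2."""
    n = 1.0 / alpha
    p = 1.0 / (1.0 + alpha * mean)
    return rng.negative_binomial(n, p)


def generate_seqc_like(seed: int = 0, config: SEQCLikeConfig | None = None) -> pd.DataFrame:
    """Generate the benchmark count table.

    Columns: ``gene_id``, ``A_1..A_5`` (condition A counts), ``B_1..B_5``
    (condition B counts), ``GT_DE`` in {TRUE, FALSE, NA} and ``spike_ratio``
    in {0.5, 0.67, 1, 2, NA}. Spike-in rows come first (``SPIKE_`` ids).
    Condition-B spike-in means equal ratio x condition-A means.
    """
    cfg = config or SEQCLikeConfig()
    rng = np.random.default_rng(seed)
    G = cfg.n_genes
    mu = rng.lognormal(cfg.mean_log_mu, cfg.mean_log_sigma, size=G)
    alpha = rng.gamma(cfg.dispersion_shape, cfg.dispersion_scale, size=G) + 1e-3

    ratio = np.ones(G)
    gt: np.ndarray = np.full(G, None, dtype=object)
    n_spike, n_null = cfg.n_spikein, cfg.n_null_spikein
    if n_spike:
        gt[:n_null] = "FALSE"
        n_de = cfg.n_de_spikein
        de_ratios = np.tile(cfg.spike_ratios, n_de // len(cfg.spike_ratios) + 1)[:n_de]
        ratio[n_null:n_spike] = de_ratios
        gt[n_null:n_spike] = "TRUE"
    # nuisance DE among background genes: truth stays NA
    n_bg = G - n_spike
    n_nuisance = int(round(cfg.nuisance_de_fraction * n_bg))
    if n_nuisance:
        idx = n_spike + rng.choice(n_bg, size=n_nuisance, replace=False)
        ratio[idx] = 2.0 ** rng.normal(0.0, cfg.nuisance_lfc_sigma, size=n_nuisance)

    r = cfg.n_replicates
    counts_a = np.column_stack([_nb_draws(rng, mu, alpha) for _ in range(r)])
    counts_b = np.column_stack([_nb_draws(rng, mu * ratio, alpha) for _ in range(r)])

    ids = [f"SPIKE_{i:03d}" if i < n_spike else f"GENE_{i:05d}" for i in range(G)]
    df = pd.DataFrame({"gene_id": ids})
    for j in range(r):
        df[f"A_{j + 1}"] = counts_a[:, j]
    for j in range(r):
        df[f"B_{j + 1}"] = counts_b[:, j]
    df["GT_DE"] = gt
    df["spike_ratio"] = np.where(np.arange(G) < n_spike, ratio, np.nan)
    return df


# ---------------------------------------------------------------------------
# the demo DE caller


DE_CALLER_MANIFEST = AppManifest(
    app_name="de_caller",
    parameters=(
        ParameterSpec("normalization", "categorical", "median_of_ratios",
                      items=("total_count", "median_of_ratios"),
                      label="Library-size normalization"),
        ParameterSpec("dispersion", "categorical", "per_gene",
                      items=("common", "per_gene"), label="Dispersion mode"),
        ParameterSpec("cpm_cutoff", "double", 1.0, min=0.0, max=10.0,
                      info="genes below this CPM in all samples are not tested"),
        ParameterSpec("p_adjust", "categorical", "BH",
                      items=("BH", "holm", "bonferroni", "none"),
                      label="P-value adjustment method"),
        ParameterSpec("fdr_threshold", "double", 0.05, min=0.001, max=0.999,
                      label="FDR threshold"),
    ),
    output_tables=("de_results",),
    emits_image=False,
)


def _size_factors(counts: np.ndarray, method: str) -> np.ndarray:
    totals = counts.sum(axis=0).astype(float)
    if totals.mean() == 0:
        return np.ones_like(totals)
    if method == "total_count":
        return totals / totals.mean()
    if method == "median_of_ratios":
        positive = (counts > 0).all(axis=1)
        if not positive.any():
            return totals / totals.mean()
        logref = np.log(counts[positive]).mean(axis=1)
        ratios = np.log(counts[positive]) - logref[:, None]
        return np.exp(np.median(ratios, axis=0))
    raise ValueError(f"unknown normalization {method!r}")


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p
    from statsmodels.stats.multitest import multipletests

    mapped = {"BH": "fdr_bh", "holm": "holm", "bonferroni": "bonferroni"}[method]
    return multipletests(p, method=mapped)[1]


def _moderate_variances(s2: np.ndarray, df_resid: int) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances (Smyth's moment fit).

    Fits a scaled inverse-chi-square prior to the observed variances via the
    moments of log s^2 and returns the posterior-mean variances together
    with the total degrees of freedom df_resid + d0. Falls back to no
    shrinkage when too few genes are available to estimate the prior.
    """
    from scipy.optimize import brentq
    from scipy.special import digamma, polygamma

    if len(s2) < 10:
        return s2, float(df_resid)
    z = np.log(s2)
    e = z - digamma(df_resid / 2.0) + np.log(df_resid / 2.0)
    excess = np.var(z, ddof=1) - polygamma(1, df_resid / 2.0)
    hi = 400.0
    if excess <= polygamma(1, hi / 2.0):
        d0 = hi  # variances essentially exchangeable: near-complete shrinkage
    else:
        d0 = brentq(lambda d: polygamma(1, d / 2.0) - excess, 0.05, hi)
    s0_sq = float(np.exp(e.mean() + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    v = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
    return v, float(df_resid + d0)


def de_caller_app(counts_table: pd.DataFrame, params: Mapping[str, Any]) -> AppResult:
    """Two-group DE test over A_* vs B_* count columns.

    Tested genes are scored by a log-ratio statistic: the difference of mean
    log normalized counts between conditions over its standard error. The
    log-scale variance follows the negative-binomial delta approximation
    var(log x) ~ alpha + 1/mu; in ``per_gene`` mode it is estimated per gene
    by the pooled sample variance across both conditions (a chi-square
    estimator, so referring the statistic to Student t with n1+n2-2 df
    keeps the test calibrated at small n); in ``common`` mode the
    dispersion component alpha is shrunk to its across-gene median and the
    statistic is referred to the normal, as common-dispersion count models
    do. Output table ``de_results`` has one row per gene with ``DE`` in
    {-1, 0, +1} (sign of the B-vs-A log-ratio for significant genes) and
    ``isDE``.
    """
    cols_a = [c for c in counts_table.columns if c.startswith("A_")]
    cols_b = [c for c in counts_table.columns if c.startswith("B_")]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicate columns per condition (A_*, B_*)")
    counts = counts_table[cols_a + cols_b].to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n1, n2 = len(cols_a), len(cols_b)

    sf = _size_factors(counts, params.get("normalization", "median_of_ratios"))
    norm = counts / sf
    totals = counts.sum(axis=0, keepdims=True)
    cpm = np.divide(counts * 1e6, totals, out=np.zeros_like(counts), where=totals > 0)
    tested = (cpm >= float(params.get("cpm_cutoff", 1.0))).any(axis=1)

    G = len(counts_table)
    de = np.zeros(G, dtype=int)
    if not tested.any():
        logger.warning("all %d genes fall below the CPM cutoff; no gene tested", G)
    else:
        la = np.log(norm[tested][:, :n1] + 0.5)
        lb = np.log(norm[tested][:, n1:] + 0.5)
        m1, m2 = la.mean(axis=1), lb.mean(axis=1)
        logratio = m2 - m1
        df_resid = n1 + n2 - 2
        # pooled log-scale variance: the moment estimate of alpha + 1/mu
        v_pooled = (la.var(axis=1, ddof=1) * (n1 - 1) + lb.var(axis=1, ddof=1) * (n2 - 1))
        v_pooled /= df_resid
        if params.get("dispersion", "per_gene") == "common":
            mean_norm = norm[tested].mean(axis=1) + 0.5
            alpha_g = np.clip(v_pooled - 1.0 / mean_norm, 1e-8, 10.0)
            v = np.median(alpha_g) + 1.0 / mean_norm
            z = logratio / np.sqrt(v * (1.0 / n1 + 1.0 / n2))
            p = 2.0 * stats.norm.sf(np.abs(z))
        else:
            v, df_total = _moderate_variances(np.maximum(v_pooled, 1e-12), df_resid)
            z = logratio / np.sqrt(v * (1.0 / n1 + 1.0 / n2))
            p = 2.0 * stats.t.sf(np.abs(z), df=df_total)
        padj = _adjust(p, params.get("p_adjust", "BH"))
        sig = padj < float(params.get("fdr_threshold", 0.05))
        de[tested] = np.where(sig, np.sign(logratio).astype(int), 0)

    out = pd.DataFrame(
        {
            "gene_id": counts_table.get("gene_id", pd.RangeIndex(G).astype(str)),
            "DE": de,
            "isDE": np.where(de != 0, "TRUE", "FALSE"),
        }
    )
    return AppResult(tables={"de_results": out})
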