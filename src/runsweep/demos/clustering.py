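"""Clustering demo app: four methods, five validity indices, one image.

For each run the app clusters the numeric columns of the input table with
the requested method and emits

* ``cluster_ids``       - one row per input row, one ``cluster_id`` column,
* ``quality_criteria``  - a single row with the five validity indices,
* an image              - 2-D embedding scatter colored by cluster.

Cluster ids are relabeled to consecutive non-negative integers; some
methods legitimately converge to fewer clusters than requested, which the
``n_class_labels`` derivation makes visible downstream.
"""

from __future__ import annotations

import logging
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ..embedding import embed_2d
from ..manifest import AppManifest, ParameterSpec
from ..sampler import AppResult
from .quality import QUALITY_METRICS, cluster_quality_metrics

logger = logging.getLogger(__name__)

__all__ = ["CLUSTERING_MANIFEST", "clustering_app", "dimred_app"]

AGGLOMERATION_METHODS = ("ward", "complete", "average", "single", "median", "centroid")

CLUSTERING_MANIFEST = AppManifest(
    app_name="clustering",
    parameters=(
        ParameterSpec("method", "categorical", "kmeans",
                      items=("kmeans", "spectral", "hierarchical", "dbscan"),
                      label="Clustering method"),
        ParameterSpec("k", "integer", 4, min=2, max=20, label="Number of clusters"),
        ParameterSpec("algorithm", "categorical", "lloyd", items=("lloyd", "elkan"),
                      info="k-means update algorithm", depends_on="method"),
        ParameterSpec("agglomeration_method", "categorical", "ward",
                      items=AGGLOMERATION_METHODS,
                      info="linkage rule for hierarchical clustering",
                      depends_on="method"),
        ParameterSpec("kernel", "categorical", "rbf", items=("rbf", "nearest_neighbors"),
                      info="affinity for spectral clustering", depends_on="method"),
        ParameterSpec("eps", "double", 3.0, min=0.1, max=10.0,
                      info="DBSCAN neighborhood radius", depends_on="method"),
        ParameterSpec("min_samples", "integer", 5, min=1, max=20,
                      info="DBSCAN core-point threshold", depends_on="method"),
        ParameterSpec("embedding", "categorical", "pca", items=("pca", "tsne"),
                      info="2-D embedding for the output image"),
        ParameterSpec("gap_references", "integer", 10, min=1, max=50,
                      info="reference draws for the gap statistic"),
        ParameterSpec("seed", "integer", 0, min=0, max=1_000_000),
    ),
    output_tables=("cluster_ids", "quality_criteria"),
    emits_image=True,
)


def _numeric_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None) -> np.ndarray:
    if columns:
        sub = table[list(columns)]
    else:
        sub = table.select_dtypes(include=[np.number])
    if sub.shape[1] == 0:
        raise ValueError("input table has no numeric columns to cluster")
    return sub.to_numpy(dtype=float)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary labels (incl. DBSCAN's -1 noise) to consecutive ints."""
    uniq = sorted(np.unique(labels))
    lookup = {c: i for i, c in enumerate(uniq)}
    return np.array([lookup[c] for c in labels], dtype=int)


def _cluster(X: np.ndarray, params: Mapping[str, Any]) -> np.ndarray:
    from scipy.cluster.hierarchy import fcluster, linkage
    from sklearn.cluster import DBSCAN, KMeans, SpectralClustering

    method = params["method"]
    k = int(params.get("k", 4))
    seed = int(params.get("seed", 0))
    if np.all(X == X[0]):
        logger.warning("all input rows identical; returning a single cluster")
        return np.zeros(len(X), dtype=int)
    if method == "kmeans":
        km = KMeans(n_clusters=k, algorithm=params.get("algorithm", "lloyd"),
                    n_init=1, random_state=seed)
        return km.fit_predict(X)
    if method == "spectral":
        sc = SpectralClustering(
            n_clusters=k, affinity=params.get("kernel", "rbf"), random_state=seed,
            assign_labels="kmeans",
            n_neighbors=min(10, len(X) - 1),
        )
        return sc.fit_predict(X)
    if method == "hierarchical":
        Z = linkage(X, method=params.get("agglomeration_method", "ward"))
        return fcluster(Z, t=k, criterion="maxclust") - 1
    if method == "dbscan":
        db = DBSCAN(eps=float(params.get("eps", 3.0)),
                    min_samples=int(params.get("min_samples", 5)))
        return db.fit_predict(X)
    raise ValueError(f"unknown clustering method {method!r}")


def _embedding_figure(coords: np.ndarray, labels: np.ndarray):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3.2, 2.6))
    ax.scatter(coords[:, 0], coords[:, 1], c=labels, cmap="tab10", s=6)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    return fig


def clustering_app(input_table: pd.DataFrame, params: Mapping[str, Any]) -> AppResult:
    X = _numeric_matrix(input_table)
    labels = _relabel(_cluster(X, params))
    seed = int(params.get("seed", 0))
    metrics = cluster_quality_metrics(
        X, labels, seed=seed, gap_references=int(params.get("gap_references", 10))
    )
    coords = embed_2d(X, params.get("embedding", "pca"), seed=seed)
    return AppResult(
        tables={
            "cluster_ids": pd.DataFrame({"cluster_id": labels}),
            "quality_criteria": pd.DataFrame([{m: metrics[m] for m in QUALITY_METRICS}]),
        },
        image=_embedding_figure(coords, labels),
    )


def dimred_app(
    table: pd.DataFrame,
    columns: Sequence[str] | None = None,
    methods: Sequence[str] = ("pca", "mds", "tsne"),
    seed: int = 0,
) -> pd.DataFrame:
    """Append 2-D projection columns of the selected numeric columns.

    For each requested method two columns are added to a copy of the table
    (``PCA1``/``PCA2``, ``MDS1``/``MDS2``, ``tSNE1``/``tSNE2``); selecting
    all three methods therefore appends six columns.
    """
    X = _numeric_matrix(table, columns)
    if len(X) < 3:
        raise ValueError("dimensionality reduction needs at least 3 rows")
    display = {"pca": "PCA", "mds": "MDS", "tsne": "tSNE"}
    out = table.copy()
    for method in methods:
        if method not in display:
            raise ValueError(f"unknown method {method!r} (legal: pca, mds, tsne)")
        coords = embed_2d(X, method, seed=seed)
        out[f"{display[method]}1"] = coords[:, 0]
        out[f"{display[method]}2"] = coords[:, 1]
    return out
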