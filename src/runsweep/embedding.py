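"""2-D embeddings shared by the derivation pass and the demo apps.

PCA and t-SNE are delegated to scikit-learn. MDS is classical (Torgerson)
scaling computed in closed form from the double-centered squared Euclidean
distance matrix: deterministic, and exact for data that is genuinely low
rank, which is what the contracts here need (duplicate rows map to identical
coordinates; planted 2-D configurations are recovered up to rotation).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = ["pca_2d", "classical_mds_2d", "tsne_2d", "embed_2d"]


def pca_2d(X: np.ndarray) -> np.ndarray:
    from sklearn.decomposition import PCA

    X = np.asarray(X, dtype=float)
    n_comp = min(2, X.shape[0], X.shape[1])
    coords = PCA(n_components=n_comp).fit_transform(X)
    if coords.shape[1] < 2:  # pad rank-deficient inputs with a zero axis
        coords = np.hstack([coords, np.zeros((coords.shape[0], 2 - coords.shape[1]))])
    return coords


def classical_mds_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:2]
    vals = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals)
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
    # fix the sign ambiguity so repeated calls agree
    for j in range(coords.shape[1]):
        k = np.argmax(np.abs(coords[:, j]))
        if coords[k, j] < 0:
            coords[:, j] *= -1
    return coords


def tsne_2d(X: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    from sklearn.manifold import TSNE

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if perplexity is None:
        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca" if X.shape[1] >= 2 else "random",
    )
    return tsne.fit_transform(X)


def embed_2d(X: np.ndarray, method: str, seed: int = 0) -> np.ndarray:
    """Dispatch on method name in {pca, mds, tsne}; returns an (n, 2) array."""
    method = method.lower()
    if method == "pca":
        return pca_2d(X)
    if method == "mds":
        return classical_mds_2d(X)
    if method == "tsne":
        return tsne_2d(X, seed=seed)
    raise ValueError(f"unknown embedding method {method!r} (legal: pca, mds, tsne)")
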