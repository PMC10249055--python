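"""Synthetic binary feature table of landscape-painting motifs.

A seeded stand-in for a catalogue of 403 paintings, each described by 67
binary features (does the scene contain a tree, an ocean, a mountain, ...).
Rows fall into four latent scene types (seascape, mountain, river/woodland,
winter) and each scene type switches on its own co-occurring block of
features, so the table carries real cluster structure for the clustering
demo to find: within a block, feature columns co-occur far more often than
across blocks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_paintings_like", "FEATURE_BLOCKS", "N_ROWS", "N_FEATURES"]

N_ROWS = 403
N_FEATURES = 67

#: planted co-occurrence blocks: one per latent scene type
FEATURE_BLOCKS: dict[str, tuple[str, ...]] = {
    "seascape": ("ocean", "waves", "beach", "surf", "cliff", "palm_trees"),
    "mountain": ("mountain", "snowy_mountain", "ridge", "peak", "conifer", "rocks"),
    "river": ("river", "deciduous", "grass", "bushes", "path", "bridge"),
    "winter": ("snow", "winter", "frozen_lake", "bare_tree", "fog", "cabin"),
}

#: features common to almost every scene, independent of type
_COMMON = ("tree", "trees", "clouds")


def _feature_names() -> list[str]:
    names = [f for block in FEATURE_BLOCKS.values() for f in block]
    names += list(_COMMON)
    i = 0
    while len(names) < N_FEATURES:
        names.append(f"motif_{i:02d}")
        i += 1
    return names[:N_FEATURES]


def generate_paintings_like(seed: int = 0) -> pd.DataFrame:
    """Return the 403 x 67 binary table with a leading ``painting_id`` column.

    Deterministic for a given seed. Block features fire with probability
    0.85 inside their scene type and 0.06 outside; common features with 0.8
    everywhere; filler motifs with 0.15 everywhere.
    """
    rng = np.random.default_rng(seed)
    names = _feature_names()
    block_names = list(FEATURE_BLOCKS)
    group_sizes = (120, 110, 90, 83)  # sums to 403
    assert sum(group_sizes) == N_ROWS
    groups = np.repeat(np.arange(len(group_sizes)), group_sizes)

    p = np.full((N_ROWS, N_FEATURES), 0.15)
    for b, block in enumerate(block_names):
        for feat in FEATURE_BLOCKS[block]:
            j = names.index(feat)
            p[:, j] = 0.06
            p[groups == b, j] = 0.85
    for feat in _COMMON:
        p[:, names.index(feat)] = 0.8

    data = (rng.random((N_ROWS, N_FEATURES)) < p).astype(int)
    df = pd.DataFrame(data, columns=names)
    df.insert(0, "painting_id", [f"P{i:03d}" for i in range(N_ROWS)])
    return df
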