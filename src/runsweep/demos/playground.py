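"""2-D toy classification datasets for the neural-network demo.

Four shapes -- two Gaussian blobs, concentric circles, an XOR quadrant
layout and two interleaved spiral arms -- each yielding 200 points split
exactly 100/100 between labels -1 and +1, with a noise dial from 0 (clean
geometry) to 50 (heavy jitter). Besides the raw coordinates, the seven
standard feature transforms are precomputed per point: X1, X2, X1^2, X2^2,
X1*X2, sin(X1), sin(X2).

Noise semantics per shape (coordinates live roughly in [-6, 6]):
gauss widens the blob standard deviation (0.5 at noise 0, 2.0 at noise 50);
circle and xor add uniform jitter of amplitude 5*noise/100; the spiral adds
uniform jitter of amplitude noise/100 (its arms are only ~1.4 apart, so the
dial spans clean to heavily mixed there too). Labels are assigned from the
clean geometry, so jitter produces genuine label noise near boundaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["generate_playground_dataset", "SHAPES", "FEATURE_COLUMNS", "N_POINTS"]

SHAPES = ("gauss", "circle", "xor", "spiral")
FEATURE_COLUMNS = ("X1", "X2", "X1^2", "X2^2", "X1*X2", "sin(X1)", "sin(X2)")
N_POINTS = 200
_HALF = N_POINTS // 2
_RADIUS = 5.0


def _gen_gauss(rng: np.random.Generator, noise: float):
    sd = 0.5 + 1.5 * noise / 50.0
    pos = rng.normal(loc=(2.0, 2.0), scale=sd, size=(_HALF, 2))
    neg = rng.normal(loc=(-2.0, -2.0), scale=sd, size=(_HALF, 2))
    return np.vstack([pos, neg]), np.r_[np.ones(_HALF), -np.ones(_HALF)]


def _gen_circle(rng: np.random.Generator, noise: float):
    def ring(n, r_lo, r_hi):
        r = rng.uniform(r_lo, r_hi, n)
        t = rng.uniform(0, 2 * np.pi, n)
        return np.column_stack([r * np.sin(t), r * np.cos(t)])

    inner = ring(_HALF, 0.0, 0.5 * _RADIUS)
    outer = ring(_HALF, 0.7 * _RADIUS, _RADIUS)
    X = np.vstack([inner, outer])
    X += rng.uniform(-_RADIUS, _RADIUS, X.shape) * noise / 100.0
    return X, np.r_[np.ones(_HALF), -np.ones(_HALF)]


def _gen_xor(rng: np.random.Generator, noise: float):
    # exactly 50 points per quadrant, padded 0.3 away from the axes
    quads = [(1, 1), (-1, -1), (1, -1), (-1, 1)]
    pts, labels = [], []
    for sx, sy in quads:
        q = rng.uniform(0.3, _RADIUS, (_HALF // 2, 2)) * np.array([sx, sy])
        pts.append(q)
        labels.append(np.full(_HALF // 2, 1.0 if sx * sy > 0 else -1.0))
    X = np.vstack(pts)
    X += rng.uniform(-_RADIUS, _RADIUS, X.shape) * noise / 100.0
    return X, np.concatenate(labels)


def _gen_spiral(rng: np.random.Generator, noise: float):
    pts, labels = [], []
    for label, phase in ((1.0, 0.0), (-1.0, np.pi)):
        i = np.arange(_HALF)
        r = i / (_HALF - 1) * _RADIUS
        t = 1.75 * i / (_HALF - 1) * 2 * np.pi + phase
        arm = np.column_stack([r * np.sin(t), r * np.cos(t)])
        arm += rng.uniform(-1.0, 1.0, arm.shape) * noise / 100.0
        pts.append(arm)
        labels.append(np.full(_HALF, label))
    return np.vstack(pts), np.concatenate(labels)


_GENERATORS = {
    "gauss": _gen_gauss,
    "circle": _gen_circle,
    "xor": _gen_xor,
    "spiral": _gen_spiral,
}


def generate_playground_dataset(shape: str, noise: float, seed: int = 0) -> pd.DataFrame:
    """Generate one dataset: 200 rows, the seven feature columns and a
    ``label`` column in {-1, +1} with exactly 100 points per label."""
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r} (legal: {SHAPES})")
    if not (0 <= noise <= 50):
        raise ValueError(f"noise must lie in [0, 50], got {noise}")
    rng = np.random.default_rng(seed)
    X, y = _GENERATORS[shape](rng, float(noise))
    x1, x2 = X[:, 0], X[:, 1]
    df = pd.DataFrame(
        {
            "X1": x1,
            "X2": x2,
            "X1^2": x1**2,
            "X2^2": x2**2,
            "X1*X2": x1 * x2,
            "sin(X1)": np.sin(x1),
            "sin(X2)": np.sin(x2),
            "label": y.astype(int),
        }
    )
    return df
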