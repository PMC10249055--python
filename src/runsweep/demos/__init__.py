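"""Bundled demo model apps and seeded synthetic-data generators.

Three desk-scale workflows exercise the full sweep pipeline end to end:

* clustering of a binary feature table with five validity indices,
* a parameterized differential-expression caller benchmarked on a
  spike-in count table with known ground truth,
* a small MLP classifier over 2-D toy datasets with per-epoch checkpoints.
"""

from __future__ import annotations

from ..manifest import AppManifest
from ..sampler import ModelApp


def get_demo_app(name: str) -> tuple[AppManifest, ModelApp]:
    """Resolve a bundled demo app by name -> (manifest, app callable)."""
    if name == "clustering":
        from .clustering import CLUSTERING_MANIFEST, clustering_app

        return CLUSTERING_MANIFEST, clustering_app
    if name == "de_caller":
        from .seqc import DE_CALLER_MANIFEST, de_caller_app

        return DE_CALLER_MANIFEST, de_caller_app
    if name == "mlp":
        from .mlp import MLP_MANIFEST, mlp_model_app

        return MLP_MANIFEST, mlp_model_app
    raise KeyError(f"unknown demo app {name!r} (available: clustering, de_caller, mlp)")


DEMO_APPS = ("clustering", "de_caller", "mlp")
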