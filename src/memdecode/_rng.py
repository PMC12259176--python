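"""Named random sub-streams derived from one root seed.

Every stochastic stage of the pipeline (image scores, trial sequence, unit
parameters, spike counts, behavior, trial subsampling, permutations,
bootstraps) pulls an independent generator keyed by a stage name, so that
changing e.g. the number of units never perturbs the behavioral draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stage *name* derived from the root *seed*."""
    if seed is None:
        raise ValueError("seed must be an integer, not None")
    key = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))
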