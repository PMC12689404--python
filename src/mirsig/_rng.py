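"""Deterministic random-stream derivation.

A single master seed drives every stochastic stage of the pipeline. Each
stage draws from its own substream, derived from the master seed and a
stage name, so adding permutations to one stage never perturbs another.
"""

from __future__ import annotations

import zlib

import numpy as np

MASTER_SEED_DEFAULT = 20250912


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for ``stage`` derived from ``master_seed``.

    The substream is seeded by (master_seed, crc32(stage)), so it is stable
    across sessions and platforms and independent of call order.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def as_rng(seed_or_rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
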