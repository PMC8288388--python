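"""Seed derivation.

All randomness flows from a single master seed.  Sub-streams are derived
with :class:`numpy.random.SeedSequence` spawn keys built from small integer
tags, so every call site is reproducible and independent.
"""

from __future__ import annotations

import numpy as np

# fixed tags for the documented derivation scheme
TAG_P300_TRAIN = 1
TAG_P300_TEST = 2
TAG_SSVEP = 3
TAG_ATTACK = 4
TAG_BASELINE = 5
TAG_MIXING = 6


def derive_rng(seed: int, *tags: int) -> np.random.Generator:
    """Generator for stream ``tags`` of master ``seed``."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(int(t) for t in tags))
    return np.random.default_rng(ss)


def derive_seed(seed: int, *tags: int) -> int:
    """A 31-bit integer sub-seed (for APIs that take a plain int seed)."""
    return int(derive_rng(seed, *tags).integers(0, 2**31 - 1))
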