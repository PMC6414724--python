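"""Seed derivation.

One master seed drives a run; every stage draws from a child generator
derived as ``SeedSequence((master, crc32(stage-key), ...))`` so stages are
independently reproducible and insensitive to the order in which other
stages consume randomness.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode())


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """Deterministic child generator for a (master seed, stage path) pair."""
    entropy = (int(master_seed) & 0xFFFFFFFF,) + tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(entropy))
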