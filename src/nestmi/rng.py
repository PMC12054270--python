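"""Counter-based seed derivation.

Every source of randomness in the package draws from a substream addressed by
a master seed plus a path of keys (replicate index, stage, imputation index,
...).  Substreams are independent and any single replicate or imputation is
reproducible in isolation, regardless of loop order or parallelism.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "seed_for"]

_MASK = 0x7FFFFFFF


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    raise TypeError(f"seed path keys must be int or str, got {type(key)!r}")


def seed_for(master_seed: int, *path) -> np.random.SeedSequence:
    """SeedSequence for the substream addressed by ``path`` under ``master_seed``."""
    entropy = [int(master_seed) & _MASK] + [_key_to_int(k) for k in path]
    return np.random.SeedSequence(entropy)


def stream(master_seed: int, *path) -> np.random.Generator:
    """A fresh Generator for the substream addressed by ``path``."""
    return np.random.default_rng(seed_for(master_seed, *path))
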