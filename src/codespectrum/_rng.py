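"""Seed-substream plumbing.

One root seed spawns named substreams so individual pipeline stages
(weights, neuron parameters, electrode layout, per-trial simulation) can be
replayed in isolation without consuming each other's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key_to_int(key: object) -> int:
    """Map an arbitrary hashable key to a stable 32-bit integer."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator for the named substream of a root seed.

    The same (seed, keys) pair always yields the same stream; distinct key
    paths yield statistically independent streams (numpy SeedSequence with a
    spawn key derived from the key path).
    """
    spawn_key = tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=spawn_key))
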