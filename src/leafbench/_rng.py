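"""Seed-stream plumbing.

All randomness in the package flows from one root integer seed.  Independent
components (species bank, per-observation pose, background clutter, split
replicates, ...) each draw from a named sub-stream so that any stage can be
re-seeded and reproduced in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def substream(root_seed: int, *keys: object) -> np.random.Generator:
    """Generator for the sub-stream named by ``keys`` under ``root_seed``.

    The same ``(root_seed, keys)`` pair always yields an identical stream;
    distinct key tuples yield statistically independent streams.
    """
    spawn_key = tuple(_key_to_int(k) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(root_seed, spawn_key=spawn_key))


def subseed(root_seed: int, *keys: object) -> int:
    """A derived 31-bit integer seed for APIs that take a plain seed."""
    ss = np.random.SeedSequence(root_seed, spawn_key=tuple(_key_to_int(k) for k in keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
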