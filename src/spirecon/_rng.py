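"""Deterministic random-stream fan-out.

One user-facing seed governs a whole run.  Module- and row-level streams are
derived by stable names / counters, so adding a pipeline stage or extending a
measurement never perturbs the randomness already consumed elsewhere.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "row_rng", "derive_seed"]

_MOD = 2**31


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) % 2**32
    digest = hashlib.blake2s(str(key).encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "little")


def substream(seed: int, *keys: str | int) -> np.random.Generator:
    """Named substream of the global seed.

    ``substream(seed, "patterns", 3)`` always yields the same generator for
    the same arguments, independent of every other substream.
    """
    entropy = [int(seed) % 2**32] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def row_rng(seed: int, label: str, row: int) -> np.random.Generator:
    """Counter-based per-row stream (Philox).

    Row ``i`` of a measurement always draws from the same stream regardless of
    how many rows are simulated, so truncating or extending the pattern set
    never re-randomizes earlier rows.
    """
    key = (int(seed) % 2**32) * 2**32 + _key_to_int(label)
    bits = np.random.Philox(key=key, counter=[0, 0, 0, int(row)])
    return np.random.Generator(bits)


def derive_seed(seed: int, *keys: str | int) -> int:
    """Small (< 2**31) integer seed derived from named keys."""
    return int(substream(seed, *keys).integers(0, _MOD))
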