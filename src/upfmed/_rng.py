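"""Deterministic random-stream derivation.

All randomness in a run flows from a single integer seed. Named
sub-streams are derived by hashing ``(seed, purpose[, participant])``
with BLAKE2, so adding or reordering stages never perturbs the draws
of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream", "spawn_seeds"]


def _digest(*parts: object) -> int:
    h = hashlib.blake2b("\x1f".join(str(p) for p in parts).encode(), digest_size=8)
    return int.from_bytes(h.digest(), "little")


def substream(seed: int, *purpose: object) -> np.random.Generator:
    """Generator for the sub-stream identified by ``purpose`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, _digest(*purpose)]))


def spawn_seeds(seed: int, n: int, purpose: str = "spawn") -> list[int]:
    """``n`` child seeds (< 2**31) derived deterministically from ``seed``."""
    rng = substream(seed, purpose)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
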