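"""Deterministic sub-seed derivation.

One master seed drives a run; every stratum / gene / predictor gets its
own independent substream derived from a stable hash of string keys, so
recomputing a single stratum in isolation reproduces exactly the numbers
of the full run, and adding a predictor does not perturb the columns of
the others.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed_sequence", "derive_rng"]


def _key_to_int(key: object) -> int:
    digest = hashlib.blake2b(repr(key).encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def derive_seed_sequence(master_seed: int, *keys: object) -> np.random.SeedSequence:
    """Build a SeedSequence from a master seed plus arbitrary hashable keys."""
    entropy = [int(master_seed) & 0xFFFFFFFFFFFFFFFF]
    entropy.extend(_key_to_int(k) for k in keys)
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Independent Generator for the substream identified by ``keys``."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *keys))
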