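"""Deterministic seed splitting.

All randomness in the package flows from one root seed.  Each stage (and each
independent draw inside a stage) derives a child generator from the root seed
plus a string key, so adding a new consumer never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed(root_seed: int, *keys: str) -> np.random.SeedSequence:
    """Derive a child seed sequence from a root seed and string keys.

    The keys are hashed with CRC32, which is stable across platforms and
    Python versions (unlike ``hash``).
    """
    entropy = [int(root_seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(k.encode("utf-8")) for k in keys)
    return np.random.SeedSequence(entropy)


def child_rng(root_seed: int, *keys: str) -> np.random.Generator:
    """A PCG64 generator deterministically derived from seed + keys."""
    return np.random.default_rng(child_seed(root_seed, *keys))


def child_int(root_seed: int, *keys: str, bound: int = 2**31 - 1) -> int:
    """A small deterministic integer seed for libraries that want an int."""
    return int(child_seed(root_seed, *keys).generate_state(1)[0] % bound)
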