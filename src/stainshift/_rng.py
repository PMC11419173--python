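"""Seed discipline: one root seed per study, named derived streams.

Every stochastic operation takes an explicit integer seed or derives one
from a parent seed plus string/integer tags, so identical inputs always
reproduce identical outputs. Derived seeds stay below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np

MAX_SEED = 2**31 - 1


def child_seed(root: int, *tags) -> int:
    """Derive a deterministic child seed from ``root`` and a tag path."""
    parts = [int(root) & 0xFFFFFFFF]
    for tag in tags:
        if isinstance(tag, (int, np.integer)):
            parts.append(int(tag) & 0xFFFFFFFF)
        else:
            parts.append(zlib.crc32(str(tag).encode("utf8")))
    seq = np.random.SeedSequence(parts)
    return int(seq.generate_state(1, np.uint32)[0]) % MAX_SEED


def rng_from(root: int, *tags) -> np.random.Generator:
    """A fresh Generator on the derived stream ``(root, *tags)``."""
    return np.random.default_rng(child_seed(root, *tags))
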