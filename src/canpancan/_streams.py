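"""Named, order-independent random streams derived from one global seed.

Every stochastic stage draws from its own child generator so that adding or
reordering stages never perturbs the numbers of another stage.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named stream."""
    return zlib.crc32(f"{int(seed)}:{name}".encode()) & 0x7FFFFFFF


def child_rng(seed: int, name: str) -> np.random.Generator:
    """A Generator seeded by (seed, name); independent of call order."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))
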