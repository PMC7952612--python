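"""Deterministic seed derivation.

One global seed deterministically derives per-module / per-stage seeds so that
re-running a single stage in isolation reproduces exactly what the full
pipeline would have fed it.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(global_seed: int, *tags: object) -> int:
    """Derive a child seed < 2**31 from a global seed and a label path.

    The same (global_seed, tags) pair always yields the same child seed;
    distinct tag paths yield (with overwhelming probability) distinct seeds.
    """
    label = "/".join(str(t) for t in tags)
    salt = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(salt,))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def rng_from(seed: int, *tags: object) -> np.random.Generator:
    """Generator seeded by :func:`derive_seed` of ``(seed, *tags)``."""
    return np.random.default_rng(derive_seed(seed, *tags))
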