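"""Named random-number streams.

All randomness in the package flows from a single integer seed. Independent
streams are derived per (stage, species, ...) name tuple via a stable hash of
the names used as a SeedSequence spawn key, so adding a species or stage does
not perturb the draws of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np


def _stable_key(name: str) -> int:
    return zlib.crc32(name.encode("utf-8"))


def child_rng(seed: int, *names: str) -> np.random.Generator:
    """A generator for the stream named by ``names`` under ``seed``."""
    key = tuple(_stable_key(n) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
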