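"""Seed plumbing: every stochastic operation draws from a child stream of one seed."""

from __future__ import annotations

import logging
import zlib

import numpy as np

logger = logging.getLogger("bsakit")


def derive_rng(seed: int, *tags: str | int) -> np.random.Generator:
    """Return a Generator for an operation, deterministically derived from ``seed``.

    Tags (operation names, replicate indices) are hashed into the seed sequence so
    distinct operations get independent streams from the same master seed.
    """
    keys = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            keys.append(zlib.crc32(t.encode()) & 0x7FFFFFFF)
        else:
            keys.append(int(t) & 0x7FFFFFFF)
    logger.debug("rng sub-seed: %s", keys)
    return np.random.default_rng(np.random.SeedSequence(keys))
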