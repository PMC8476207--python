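"""Named random substreams derived from a single session seed.

Every stochastic component (stimulus event times, per-unit spike sampling,
lever trajectories, ...) draws from its own child generator, keyed by a
stable name, so components are reproducible independently of one another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The child entropy mixes the session seed with a CRC32 of the name, so
    renaming or reordering other substreams never perturbs this one.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, key]))


def as_generator(seed_or_rng) -> np.random.Generator:
    """Accept either an integer seed or an existing Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
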