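"""Deterministic seeding: one top-level seed, named substreams.

Every stochastic routine takes an integer seed and derives its generator via
``substream(seed, "name", ...)`` so results are replayable independent of
execution order, and no module ever touches numpy's global random state.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(part) -> int:
    if isinstance(part, (int, np.integer)):
        return int(part) & 0xFFFFFFFF
    return zlib.crc32(str(part).encode("utf-8"))


def substream(seed: int, *names) -> np.random.Generator:
    """Generator for the named substream of a top-level seed.

    Name parts may be strings or integers (e.g. a candidate sample size),
    hashed into the numpy ``SeedSequence`` spawn key.
    """
    ss = np.random.SeedSequence(int(seed), spawn_key=tuple(_key(p) for p in names))
    return np.random.default_rng(ss)
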