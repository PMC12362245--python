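"""Seed-substream management.

Every stochastic stage of the pipeline draws from its own substream so that
stages are individually reproducible and insensitive to the order in which
other stages consume random numbers.  Substreams are derived from the user
seed plus small integer tags via :class:`numpy.random.SeedSequence` spawn
keys.  String tags (e.g. condition labels) are hashed with CRC-32 so the
mapping is stable across processes and Python versions.
"""

from __future__ import annotations

import zlib

import numpy as np

# module tags for spawn keys; never reuse a tag for a new purpose
TAG_DIRICHLET = 1
TAG_SCALE = 2
TAG_EFFECT = 3
TAG_BACKBONE = 4
TAG_PERMUTE = 5
TAG_THINNING = 6
TAG_BENCHMARK = 7


def _as_key(tag: int | str) -> int:
    if isinstance(tag, str):
        return zlib.crc32(tag.encode("utf-8"))
    return int(tag)


def substream(seed: int, *tags: int | str) -> np.random.Generator:
    """Return a generator for the substream identified by ``seed`` and tags."""
    key = tuple(_as_key(t) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))
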