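"""Seed fan-out: one top-level seed, named independent substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a generator for the named substream of ``seed``.

    Streams with distinct names are statistically independent; the same
    (seed, name) pair always yields the same stream.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))
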