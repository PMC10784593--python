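"""Seed fan-out: one global seed, named independent substreams."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from (seed, name).

    The name is hashed with CRC-32 so substreams are stable across runs and
    platforms; different names give statistically independent streams.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))
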