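"""Seed handling.

A single integer seed drives every stochastic stage.  Each stage draws from a
named sub-stream derived from (seed, stage-name), so stages are independently
reproducible: re-running one stage with the same seed gives the same numbers
regardless of what other stages did with the generator.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named sub-stream of ``seed``.

    The stream key is a CRC32 of ``name``; it is stable across sessions and
    platforms (unlike ``hash``).
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
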