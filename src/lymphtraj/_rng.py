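"""Seeded random-number streams.

One global seed keys the whole run; every stage draws from its own named
substream so that changing the amount of randomness one stage consumes never
perturbs another stage's draws.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``seed``.

    The stream key is ``(seed, crc32(name))`` fed to the default bit
    generator, so substreams are stable across sessions and platforms.
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])
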