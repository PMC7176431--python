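"""Seeded random-number substreams.

All randomness in the package flows from one root seed through named
substreams, so adding a pipeline stage never perturbs the draws of another
stage and every run is reproducible bit-for-bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(root_seed: int, *names: str | int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream is a pure function of ``(root_seed, names)``: the root seed is
    combined with a CRC32 hash of each name into a SeedSequence, so streams
    for distinct names are statistically independent.
    """
    keys = [int(root_seed) & 0x7FFFFFFF]
    for name in names:
        if isinstance(name, int):
            keys.append(name & 0xFFFFFFFF)
        else:
            keys.append(zlib.crc32(str(name).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(keys))
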