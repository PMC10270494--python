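"""Seeded random-number substreams.

All randomness in the package flows from a single integer seed. Each stage
draws from a named substream so that, e.g., changing how many genes the
transcriptome simulator emits cannot perturb the 16S count draws.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """A generator keyed by ``(seed, name)``; same pair, same stream."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )
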