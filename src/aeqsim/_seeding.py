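"""Deterministic fan-out of one global seed into named substreams.

Every stochastic component draws from a stream keyed by (global seed, name
path). The derivation is ``SeedSequence([seed, crc32(name_0), crc32(name_1),
...])``, so adding a new component never perturbs existing streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["seed_sequence", "substream"]


def seed_sequence(seed: int, *names: str) -> np.random.SeedSequence:
    """Build the seed sequence for a named substream of ``seed``."""
    entropy = [int(seed)] + [zlib.crc32(str(n).encode("utf-8")) for n in names]
    return np.random.SeedSequence(entropy)


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a ``numpy`` Generator for the named substream of ``seed``."""
    return np.random.default_rng(seed_sequence(seed, *names))
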