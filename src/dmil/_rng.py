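"""Seed fan-out: one top-level seed expands into independent named streams."""

from __future__ import annotations

import zlib

import numpy as np


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for stream `name` derived from the top-level seed.

    The stream key hashes the name (CRC-32) so adding a new named stream never
    perturbs existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
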