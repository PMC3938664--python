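"""Deterministic seed derivation.

One master seed fans out into independent per-stage streams via
``numpy.random.SeedSequence`` keyed on stable string tags, so any stage of a
pipeline can be re-run in isolation with the same stream it saw inside the
full run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _tag_entropy(tag: str) -> int:
    return zlib.crc32(tag.encode("utf-8"))


def derive_seed(master: int, *tags: str | int) -> int:
    """Derive a child seed (< 2**31) from *master* and a sequence of tags."""
    entropy = [int(master) & 0xFFFFFFFF]
    for t in tags:
        entropy.append(_tag_entropy(str(t)))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1)[0] % (2**31))


def derive_rng(master: int, *tags: str | int) -> np.random.Generator:
    """A ``numpy.random.Generator`` seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *tags))
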