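"""Seed plumbing: one root integer seed, stable per-entity sub-streams."""

from __future__ import annotations

from zlib import crc32

import numpy as np


def child_rng(seed: int, *names: object) -> np.random.Generator:
    """Derive a generator from ``seed`` and a path of string-able names.

    Sub-streams are keyed by CRC32 of the names, so the stream an entity
    (strain, family, read) receives does not depend on iteration order.
    """
    spawn_key = tuple(crc32(str(n).encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=spawn_key))
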