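"""Deterministic derivation of per-stage RNG seeds from one master seed.

A single integer seed expands into independent per-stage streams via
``numpy.random.SeedSequence`` spawn keys; stage names are hashed with CRC32 so
the mapping is stable across processes and platforms.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def derive_seed(master: int, *path: str | int) -> int:
    """Derive a 32-bit child seed from ``master`` and a path of stage labels."""
    key = tuple(
        p if isinstance(p, int) else zlib.crc32(p.encode("utf-8")) for p in path
    )
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=key)
    return int(ss.generate_state(1, np.uint32)[0])


def derive_rng(master: int, *path: str | int) -> np.random.Generator:
    """Generator seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master, *path))
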