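"""Shared helpers: deterministic sub-seeding and small numerics."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng", "sigmoid"]


def child_seed(seed: int, *keys: str | int) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a master seed and keys.

    Every stochastic stage of the pipeline derives its own stream this way,
    so modules are independently reproducible under one global seed.
    """
    parts = [int(seed) & 0xFFFFFFFF]
    for k in keys:
        if isinstance(k, str):
            parts.append(zlib.crc32(k.encode("utf-8")))
        else:
            parts.append(int(k) & 0xFFFFFFFF)
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *keys))


def sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out
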