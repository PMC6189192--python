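"""Seed streams and small shared numerics."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.stats import binom

_MOD = 2**31 - 1


def stream_tag(name: str) -> int:
    """Stable 31-bit tag for a named random stream."""
    return zlib.crc32(name.encode("utf8")) & _MOD


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Generator for a named stream derived from a master seed.

    Stages consuming different stream names are statistically independent, so
    any stage can be rerun in isolation and reproduce its in-pipeline draws.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % _MOD, stream_tag(stream)]))


def derive_seed(seed: int, stream: str) -> int:
    """A plain integer seed (< 2**31) for a named sub-stream."""
    return int(rng_for(seed, stream).integers(0, _MOD))


def binomial_interval(n: int, p: float, conf: float = 0.99) -> tuple[float, float]:
    """Two-sided equal-tail binomial interval for an observed rate at n trials."""
    lo = binom.ppf((1.0 - conf) / 2.0, n, p) / n
    hi = binom.ppf(1.0 - (1.0 - conf) / 2.0, n, p) / n
    return float(lo), float(hi)
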