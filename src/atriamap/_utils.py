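"""Shared helpers: deterministic seed derivation and error types."""

from __future__ import annotations

import zlib

import numpy as np

_SEED_MOD = 2**31 - 1


class ConfigError(ValueError):
    """A configuration object violates one of its invariants."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


def derive_seed(seed: int, tag: str) -> int:
    """Mix a global seed with a string tag into an independent stream seed.

    Stage/sample tags give every random consumer its own reproducible stream,
    so stages can be rerun in isolation without replaying earlier draws.
    The result is always in [0, 2**31), safe for any RNG constructor.
    """
    return (int(seed) * 0x9E3779B1 + zlib.crc32(tag.encode("utf-8"))) % _SEED_MOD


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """A numpy Generator seeded from ``derive_seed(seed, tag)``."""
    return np.random.default_rng(derive_seed(seed, tag))
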