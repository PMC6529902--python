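"""Seed plumbing: every stochastic stage draws from its own named stream.

A (global seed, stage name) pair maps to an independent ``numpy`` Generator,
so adding draws to one stage never perturbs another and the whole pipeline is
reproducible from one integer.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng"]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic generator for a named pipeline stage."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(stage.encode())]))
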