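"""Small shared helpers."""

from __future__ import annotations

import math

import numpy as np


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero.

    Python's built-in ``round`` banker-rounds; test-set sizes and top-k
    cutoffs use the conventional half-away rule instead.
    """
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def spawn_seed(master: int, *key: int) -> int:
    """Derive a child seed (< 2**31) from a master seed and an integer key.

    Uses numpy's SeedSequence spawn-key mechanism so that derived streams
    are independent and the rule is stable across runs and platforms.
    """
    ss = np.random.SeedSequence(master, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))
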