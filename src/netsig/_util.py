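"""Shared helpers: seeded RNG derivation and small validators."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "stage_seed", "check_aligned"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage integer seed (< 2**31) from a base seed."""
    return int(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]).generate_state(1)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A Generator whose stream depends only on (seed, stage name)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())]))


def check_aligned(index_a, index_b, what: str = "gene sets") -> None:
    """Raise if two label sequences differ, naming the symmetric difference."""
    a, b = list(index_a), list(index_b)
    if a == b:
        return
    sym = sorted(set(a) ^ set(b))
    if sym:
        raise ValueError(f"mismatched {what}; symmetric difference: {sym[:20]}" + (" ..." if len(sym) > 20 else ""))
    raise ValueError(f"mismatched {what}: same labels but different order")
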