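"""Deterministic seed derivation for nested simulation components."""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(base: int, *key: int) -> int:
    """Derive a child seed (< 2**31) from a base seed and an integer key path.

    Uses :class:`numpy.random.SeedSequence` spawn keys, so children are
    decorrelated and the mapping is stable across platforms and runs.
    """
    ss = np.random.SeedSequence(
        entropy=int(base) & 0x7FFFFFFF, spawn_key=tuple(int(k) for k in key)
    )
    return int(ss.generate_state(1, np.uint32)[0] % (2**31))
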