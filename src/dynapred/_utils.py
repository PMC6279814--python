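"""Shared small helpers."""

from __future__ import annotations

import numpy as np

_SEED_CAP = 2**31 - 1


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from a master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) % _SEED_CAP for s in ss.generate_state(n, dtype=np.uint64)]
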