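"""Deterministic derivation of per-task RNG seeds from one master seed.

Every stochastic stage (detector runs, replicates, permutations) receives a
seed derived from the master seed and its position in the experiment, so a
single integer reproduces an entire run while replicates stay independent.
"""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed"]


def derive_seed(master: int, *indices: int) -> int:
    """A reproducible child seed < 2**31 for the task at ``indices``."""
    ss = np.random.SeedSequence(int(master), spawn_key=tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] % (2**31))
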