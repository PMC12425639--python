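"""Deterministic seed derivation.

Every source of randomness in the package descends from one integer root seed
through :func:`child_seed`, so that any sub-computation (dataset ``i``,
repetition ``j``) can be reproduced in isolation and results are independent
of execution order.
"""

from __future__ import annotations

import numpy as np

# sklearn and friends want seeds < 2**31
_SEED_MOD = 2**31


def child_seed(root: int, *key: int) -> int:
    """Derive a deterministic child seed from ``root`` and an integer key path."""
    ss = np.random.SeedSequence(entropy=int(root), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % _SEED_MOD)


def rng_from(root: int, *key: int) -> np.random.Generator:
    """A PCG64 generator seeded from the (root, key) path."""
    return np.random.default_rng(child_seed(root, *key))
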