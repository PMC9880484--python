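"""Stable child-seed derivation.

Every stochastic step derives its own seed from a base seed plus string
tokens (plot id, predictor group, target name, repeat index, ...) so that
results do not depend on iteration order or parallel scheduling.
"""

from __future__ import annotations

import hashlib

import numpy as np


def stable_seed(base_seed: int, *tokens: object) -> int:
    """Derive a deterministic 32-bit seed from a base seed and tokens."""
    h = hashlib.blake2b(digest_size=8)
    h.update(str(int(base_seed)).encode())
    for t in tokens:
        h.update(b"\x1f")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big")


def child_rng(base_seed: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(stable_seed(base_seed, *tokens))
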