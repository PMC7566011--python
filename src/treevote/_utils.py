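"""Small shared helpers: deterministic seed fan-out."""

from __future__ import annotations

import hashlib

import numpy as np


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a master seed by stable hashing.

    Keeps every source of randomness traceable to one master seed while
    decoupling stages (changing the tree count must not shift the
    classifier's draws).  Result is always in [0, 2^31).
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(master_seed, stage))
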