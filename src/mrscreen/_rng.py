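"""Counter-based per-variant random streams.

Every stochastic component draws from a Philox stream keyed by (seed,
variant id), so simulated tables and simulation p-values are reproducible
and independent of row order.
"""

from __future__ import annotations

import hashlib

import numpy as np


def variant_rng(seed: int, variant_id: str, salt: str = "") -> np.random.Generator:
    digest = hashlib.blake2b(
        (salt + variant_id).encode(),
        digest_size=8,
        key=int(seed).to_bytes(8, "little", signed=False),
    ).digest()
    return np.random.Generator(np.random.Philox(key=int.from_bytes(digest, "little")))


def child_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent 31-bit child seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]
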