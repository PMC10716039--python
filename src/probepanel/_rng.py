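"""Deterministic random-stream derivation.

All randomness in the package flows from one master seed. Substreams for
traces, events and reads are derived by hashing string tokens, so adding a
probe or a trace never reshuffles the draws of the others.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master_seed: int, *tokens: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and string tokens."""
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for tok in tokens:
        h.update(b"\x00")
        h.update(str(tok).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


def derive_rng(master_seed: int, *tokens: str) -> np.random.Generator:
    """A :class:`numpy.random.Generator` seeded from hashed tokens."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) % (2**31), derive_seed(master_seed, *tokens)])
    )
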