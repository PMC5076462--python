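"""Small shared helpers (deterministic seed derivation)."""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31.

    Every stochastic pipeline stage draws its seed from the master seed
    plus its stage name, so stages have independent, reproducible streams.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)
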