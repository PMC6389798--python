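"""Small shared helpers."""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed below 2**31 from a master seed and string labels.

    Used to give every stochastic stage (and every (community, cohort)
    permutation stream) its own reproducible RNG, so adding or reordering
    work units never perturbs another unit's draws.
    """
    h = hashlib.sha256()
    h.update(str(int(master_seed)).encode())
    for p in parts:
        h.update(b"\x00" + str(p).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
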