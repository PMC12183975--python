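"""Deterministic sub-seed derivation.

All randomness in the pipeline flows from one master seed; each stage / ROI /
subject draws its own seed from the master via a stable hash, so partial
reruns and parallel execution reproduce the same streams regardless of order.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *keys: object) -> int:
    """A sub-seed in [0, 2^31) derived from the master seed and string keys."""
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for k in keys:
        h.update(b"|")
        h.update(str(k).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
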