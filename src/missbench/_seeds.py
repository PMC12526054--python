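"""Deterministic seed derivation for nested pipeline stages."""

from __future__ import annotations

import hashlib


def child_seed(*parts: object) -> int:
    """Derive a stable sub-seed (< 2**31) from a master seed and string keys.

    Uses blake2b over the joined key path, so results are independent of
    PYTHONHASHSEED and identical across platforms and runs.
    """
    key = "/".join(str(p) for p in parts).encode()
    digest = hashlib.blake2b(key, digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)
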