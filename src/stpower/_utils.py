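"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(*parts) -> int:
    """Derive a stable 31-bit seed from arbitrary hashable parts.

    Used to give every simulation cell / repeat its own independent,
    order-invariant stream: the seed depends only on the values passed,
    not on execution order.
    """
    token = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(token.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def half_up(x: float) -> int:
    """Round half away from zero for non-negative x (3.5 -> 4, 2.4 -> 2)."""
    import math

    return int(math.floor(x + 0.5))
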