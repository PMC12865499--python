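"""Deterministic seed derivation.

Every stochastic stage derives its own integer seed from one master seed and
a tuple of string/int tokens (stage name, scenario, slice, set index, ...),
so the full pipeline is reproducible from a single number and stages can be
re-run independently without sharing generator state.
"""

from __future__ import annotations

import hashlib


def derive_seed(master: int, *tokens: object) -> int:
    """A stable child seed in [0, 2^31) from a master seed and tokens."""
    key = f"{int(master)}|" + "|".join(repr(t) for t in tokens)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
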