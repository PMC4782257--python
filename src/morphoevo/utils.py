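"""Small shared helpers."""

from __future__ import annotations

import hashlib


def derive_seed(base: int, *tags) -> int:
    """Derive a reproducible child seed (< 2**31) from a base seed and tags.

    Hash-based, so the result does not depend on the order in which other
    child seeds are derived elsewhere in a run.
    """
    h = hashlib.sha256()
    h.update(str(int(base)).encode())
    for t in tags:
        h.update(b"|")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)
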