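"""Small shared helpers (seed derivation)."""

from __future__ import annotations

import zlib


def derive_seed(global_seed: int, *tokens: object) -> int:
    """Deterministically derive a sub-seed from a global seed and tokens.

    Uses CRC32 of the textual key so the result is stable across runs and
    platforms and fits in a 31-bit non-negative integer (valid numpy seed).
    """
    key = ":".join([str(int(global_seed))] + [str(t) for t in tokens])
    return zlib.crc32(key.encode("utf-8")) % (2**31)
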