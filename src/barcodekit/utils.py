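"""Small shared helpers (seed derivation)."""

from __future__ import annotations

import zlib


def derive_seed(seed: int, label: str) -> int:
    """Deterministic per-operation seed derived from a global seed and a label.

    Keeps independent substreams for the different stochastic steps of a run
    while the whole pipeline stays reproducible from one integer.  The result
    is always below 2**31.
    """
    return (int(seed) * 2654435761 + zlib.crc32(label.encode())) % (2**31 - 1)
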