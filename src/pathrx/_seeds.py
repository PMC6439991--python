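"""Deterministic seed derivation from a single master seed."""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31  # downstream libraries want plain 32-bit-safe ints


def derive_seed(master: int, *tokens) -> int:
    """Derive a stable sub-seed from ``master`` and string/int tokens.

    Built on :class:`numpy.random.SeedSequence` so sub-streams for
    different tokens (e.g. meta path id + fold index) are statistically
    independent yet fully reproducible.
    """
    key = tuple(
        t if isinstance(t, (int, np.integer)) else zlib.crc32(str(t).encode())
        for t in tokens
    )
    ss = np.random.SeedSequence(entropy=int(master), spawn_key=key)
    return int(ss.generate_state(1)[0] % _MOD)
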