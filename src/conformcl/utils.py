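"""Deterministic seed fan-out shared by all stochastic components."""

from __future__ import annotations

import hashlib


def derive_seed(seed: int, *labels: str | int) -> int:
    """Derive a named substream seed (< 2^31) from a global seed.

    One global seed fans out to conformer embedding, pair sampling,
    augmentation, weight init and shuffling through distinct labels, so runs
    are reproducible end to end while substreams stay independent.
    """
    key = f"{int(seed)}:" + ":".join(str(x) for x in labels)
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
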