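"""Deterministic seed derivation.

One master seed drives the whole pipeline; each stage (sharding,
equilibration, splitting, oracle noise, ...) draws its own sub-seed from a
named stream so stages can be re-run independently without perturbing each
other's randomness.
"""

import hashlib

_MOD = 2**31


def derive_seed(master: int, *names: object) -> int:
    """Derive a sub-seed < 2**31 from a master seed and a stream name."""
    text = ":".join([str(int(master))] + [str(n) for n in names])
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def stable_hash(text: str) -> int:
    """Platform-independent non-negative hash of a string (< 2**31)."""
    return int.from_bytes(hashlib.sha256(text.encode("utf-8")).digest()[:8], "big") % _MOD
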