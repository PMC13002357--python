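"""Deterministic per-stage seed derivation.

A single run seed fans out into independent per-stage seeds by hashing the
stage name (and any extra integer qualifiers) together with the run seed.
blake2s is used so the rule is stable across platforms and Python builds
(unlike ``hash()``).
"""

from __future__ import annotations

import hashlib


def derive_seed(run_seed: int, *stage) -> int:
    """Derive a stage seed in [0, 2^31) from a run seed and stage labels."""
    key = ":".join([str(int(run_seed))] + [str(s) for s in stage])
    digest = hashlib.blake2s(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
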