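"""Deterministic seed fan-out.

A single master seed is expanded into per-stage / per-fold / per-feature-set child
seeds by hashing the token path, so that partial re-runs (or adding folds) never
perturb seeds already handed out elsewhere in the pipeline.
"""

import hashlib

_MOD = 2**31 - 1


def child_seed(master: int, *tokens) -> int:
    """Derive a stable child seed (< 2**31) from a master seed and a token path.

    Tokens may be strings, ints, or tuples thereof; the mapping depends only on
    their repr, never on process state.
    """
    payload = repr((int(master),) + tuple(tokens)).encode()
    digest = hashlib.blake2b(payload, digest_size=8).digest()
    return int.from_bytes(digest, "big") % _MOD
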