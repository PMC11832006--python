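"""Deterministic sub-seed derivation.

One user-facing seed streams per-operation sub-seeds so that stochastic
stages (permutation tests, bootstraps, simulators) are reproducible and
mutually independent: changing the number of draws in one stage does not
shift the random stream of another.
"""

import hashlib


def subseed(seed: int, *names: object) -> int:
    """Derive a sub-seed below 2**31 from ``seed`` and a name path.

    The derivation is a SHA-256 hash of the textual key, so it is stable
    across processes and platforms (unlike :func:`hash`).
    """
    key = ":".join([str(int(seed))] + [str(n) for n in names])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
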