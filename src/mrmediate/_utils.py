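"""Small shared helpers: seed derivation and allele constants."""

from __future__ import annotations

import hashlib

VALID_BASES = ("A", "C", "G", "T")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: z for a two-sided 95% interval; fixed so odds-ratio CIs are reproducible
#: to the last digit across platforms.
Z95 = 1.959964


def is_palindromic(ea: str, oa: str) -> bool:
    """True when the two alleles are strand complements (A/T or C/G)."""
    return COMPLEMENT.get(ea) == oa


def derive_seed(global_seed: int, label: str) -> int:
    """Derive a stage seed from one global seed and a stage label.

    Deterministic and stable across runs/platforms: SHA-256 of
    ``"{global_seed}:{label}"`` reduced mod 2**31. Lets any stage be rerun in
    isolation with the seed it had inside the full pipeline.
    """
    digest = hashlib.sha256(f"{global_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
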