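"""Low-level nucleotide-string helpers shared across the pipeline.

All internal processing is done on the DNA alphabet (U normalised to T);
serialisation back to RNA is the inverse mapping, so the round trip is exact.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTU")


def normalize(seq: str) -> str:
    """Uppercase and map U->T so every downstream comparison is DNA-space."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Inverse of :func:`normalize` for DNA-space sequences (T->U)."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_valid(seq: str) -> bool:
    """True iff non-empty and drawn from the unambiguous A/C/G/T/U alphabet."""
    return bool(seq) and set(seq.upper()) <= VALID_BASES


def hamming(a: str, b: str) -> int:
    """Substitution count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
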