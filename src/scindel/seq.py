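"""Small DNA sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC codes we need for PAM patterns (N is the only degenerate base used
# by the default NGG pattern, but the full table costs nothing).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved, N allowed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def matches_pattern(seq: str, pattern: str) -> bool:
    """True if ``seq`` matches an IUPAC ``pattern`` of the same length."""
    if len(seq) != len(pattern):
        return False
    return all(b in IUPAC.get(p, "") for b, p in zip(seq, pattern))


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of ``length`` bases."""
    return "".join(rng.choice(list(DNA_ALPHABET), size=length))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
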