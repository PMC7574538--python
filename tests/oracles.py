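"""Independent reference implementations used to cross-check the package.

These are deliberately written as plain, slow, obviously-correct code
paths that share nothing with the implementations they validate.
"""

from __future__ import annotations


def bruteforce_semiglobal_score(read: str, ref: str, match: int, mismatch: int,
                                gap_open: int, gap_extend: int) -> int:
    """Three-state affine-gap DP over explicit Python lists.

    Global in the read, free at both reference ends.  A gap of length L
    costs gap_open + L * gap_extend.
    """
    m, n = len(read), len(ref)
    NEG = float("-inf")
    # state matrices indexed [i][j]: best score of aligning read[:i] with
    # some suffix-anchored prefix of ref ending at j, by last-op state
    M = [[NEG] * (n + 1) for _ in range(m + 1)]
    D = [[NEG] * (n + 1) for _ in range(m + 1)]
    I = [[NEG] * (n + 1) for _ in range(m + 1)]
    for j in range(n + 1):
        M[0][j] = 0.0  # free leading reference skip
    for i in range(1, m + 1):
        for j in range(n + 1):
            I[i][j] = max(I[i - 1][j] - gap_extend,
                          max(M[i - 1][j], D[i - 1][j]) - gap_open - gap_extend)
            if j >= 1:
                s = match if read[i - 1] == ref[j - 1] else -mismatch
                M[i][j] = max(M[i - 1][j - 1], D[i - 1][j - 1],
                              I[i - 1][j - 1]) + s
                D[i][j] = max(D[i][j - 1] - gap_extend,
                              max(M[i][j - 1], I[i][j - 1])
                              - gap_open - gap_extend)
    return int(max(max(M[m][j], D[m][j], I[m][j]) for j in range(n + 1)))


def literal_zygosity(pct_modified: float, heterozygosity: float) -> str:
    """Word-for-word transcription of the classification rules:

    cells with < 20% modified alleles are WT/WT; cells with >= 20% and
    < 80% modified alleles are heterozygous WT/Mut; for cells with
    >= 80% modified alleles, those with >= 20% heterozygosity are
    heterozygous Mut/Mut2 and those with < 20% are homozygous Mut/Mut.
    """
    if pct_modified < 20:
        return "WT/WT"
    if 20 <= pct_modified < 80:
        return "WT/Mut"
    if pct_modified >= 80 and heterozygosity >= 20:
        return "Mut/Mut2"
    return "Mut/Mut"


def left_shift_deletion(ref: str, start: int, length: int) -> int:
    """Leftmost equivalent placement of deleting ref[start:start+length]."""
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def left_shift_insertion(ref: str, point: int, ins: str) -> tuple[int, str]:
    """Leftmost equivalent placement of inserting ``ins`` at ``point``."""
    while point > 0 and ins[-1] == ref[point - 1]:
        ins = ref[point - 1] + ins[:-1]
        point -= 1
    return point, ins
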