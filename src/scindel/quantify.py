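"""Per-(cell, amplicon) edit quantification within the cleavage window.

A read counts as *modified* when an indel touches the quantification
window around the predicted Cas9 cut site: deletions by half-open
interval intersection, insertions when the insertion point falls inside
the closed window (so an insertion exactly at a window boundary counts).
Substitutions are ignored by default — the assay targets NHEJ indels and
counting substitutions would let sequencer error inflate modification —
but can be enabled.

Alleles are keyed by the read sequence projected onto the window plus a
flanking margin, so errors far from the cut do not fragment alleles.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .align import (DEFAULT_SCORING, AlignmentScoring, ReadAlignment,
                    align_semiglobal, assign_amplicon)
from .panel import Amplicon, Panel

#: Bases of reference flank on each side of the window that take part in
#: the allele identity.
ALLELE_FLANK = 10

DEFAULT_MIN_AMPLICON_READS = 5


def indel_hits_window(kind: str, start: int, length: int,
                      window: tuple[int, int]) -> bool:
    """Window rule for a single left-normalized indel.

    ``kind`` is "D" (start = first deleted ref base) or "I" (start = the
    inter-base insertion point).  Deletions intersect the half-open
    window; insertion points are tested against the closed window.
    """
    lo, hi = window
    if kind == "D":
        return start < hi and start + length > lo
    if kind == "I":
        return lo <= start <= hi
    raise ValueError(f"not an indel op: {kind!r}")


def classify_read(alignment: ReadAlignment, amplicon: Amplicon,
                  count_substitutions: bool = False) -> bool:
    """True if the aligned read is modified within the amplicon's window."""
    window = amplicon.window
    if window is None:
        raise ValueError(
            f"{amplicon.amplicon_id}: control amplicon has no quantification window"
        )
    lo, hi = window
    for op, length, pos in alignment.ops:
        if op == "D" and indel_hits_window("D", pos, length, window):
            return True
        if op == "I" and indel_hits_window("I", pos, length, window):
            return True
        if count_substitutions and op == "X" and pos < hi and pos + length > lo:
            return True
    return False


def window_allele(alignment: ReadAlignment, amplicon: Amplicon, read_seq: str,
                  flank: int = ALLELE_FLANK) -> str:
    """Project the read onto the window +/- ``flank`` reference interval.

    Deleted reference positions appear as ``-``, inserted read bases are
    included at their insertion point, and reference positions not
    covered by the alignment appear as ``.``.  The resulting string is
    the allele identity for tabulation.
    """
    window = amplicon.window
    if window is None:
        raise ValueError(f"{amplicon.amplicon_id}: control amplicon has no window")
    lo = max(0, window[0] - flank)
    hi = min(len(amplicon.ref_seq), window[1] + flank)
    pieces: dict[int, str] = {}
    inserts: dict[int, str] = defaultdict(str)
    read_cursor = 0
    for op, length, pos in alignment.ops:
        if op in ("M", "X"):
            for k in range(length):
                if lo <= pos + k < hi:
                    pieces[pos + k] = read_seq[read_cursor + k]
            read_cursor += length
        elif op == "D":
            for k in range(length):
                if lo <= pos + k < hi:
                    pieces[pos + k] = "-"
        else:  # insertion
            if lo <= pos <= hi:
                inserts[pos] += read_seq[read_cursor:read_cursor + length]
            read_cursor += length
    out = []
    for p in range(lo, hi + 1):
        if p in inserts:
            out.append(inserts[p].lower())
        if p < hi:
            out.append(pieces.get(p, "."))
    return "".join(out)


@dataclass
class Allele:
    """One observed allele at a cell-amplicon."""

    allele_seq: str
    modified: bool
    count: int
    frequency: float


@dataclass
class CellAmpliconSummary:
    """Summary statistics for one cell at one amplicon."""

    barcode: str
    amplicon_id: str
    n_reads: int
    pct_modified: float
    allele1: Optional[Allele] = None
    allele2: Optional[Allele] = None

    @property
    def heterozygosity(self) -> float:
        """Frequency of the second-most-frequent allele, in percent."""
        return 100.0 * self.allele2.frequency if self.allele2 else 0.0


def summarize_cell_amplicon(barcode: str, amplicon_id: str,
                            read_calls: Iterable[tuple[bool, str]],
                            min_reads: int = DEFAULT_MIN_AMPLICON_READS,
                            ) -> Optional[CellAmpliconSummary]:
    """Tabulate alleles for one (cell, amplicon) group.

    ``read_calls`` is an iterable of ``(modified, allele_seq)`` per read.
    Returns None (NO_CALL) below ``min_reads``.  Ties in allele counts
    are broken lexicographically by allele sequence.
    """
    calls = list(read_calls)
    n = len(calls)
    if n < min_reads:
        return None
    n_modified = sum(1 for mod, _ in calls if mod)
    counts: Counter = Counter(seq for _, seq in calls)
    mod_by_seq: dict[str, bool] = {}
    for mod, seq in calls:
        mod_by_seq.setdefault(seq, mod)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    alleles = [Allele(seq, mod_by_seq[seq], c, c / n) for seq, c in ranked[:2]]
    return CellAmpliconSummary(
        barcode=barcode,
        amplicon_id=amplicon_id,
        n_reads=n,
        pct_modified=100.0 * n_modified / n,
        allele1=alleles[0] if alleles else None,
        allele2=alleles[1] if len(alleles) > 1 else None,
    )


def build_edit_matrix(summaries: Iterable[CellAmpliconSummary],
                      coverage: Optional[dict] = None,
                      cells: Optional[list] = None,
                      amplicons: Optional[list] = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compile summaries into (pct_modified matrix, coverage matrix).

    Matrix entries are NaN (MISSING) where no summary was emitted; the
    coverage matrix, when a raw ``(barcode, amplicon) -> n_reads``
    mapping is supplied, also covers groups below the read cutoff.
    """
    seen = set()
    records = []
    for s in summaries:
        key = (s.barcode, s.amplicon_id)
        if key in seen:
            raise ValueError(f"duplicate summary for cell/amplicon {key}")
        seen.add(key)
        records.append((s.barcode, s.amplicon_id, s.pct_modified, s.n_reads))
    df = pd.DataFrame(records,
                      columns=["barcode", "amplicon_id", "pct_modified", "n_reads"])
    pct = df.pivot(index="barcode", columns="amplicon_id", values="pct_modified")
    cov = df.pivot(index="barcode", columns="amplicon_id", values="n_reads")
    if coverage is not None:
        cov_df = pd.Series(coverage).rename_axis(["barcode", "amplicon_id"]) \
            .unstack("amplicon_id")
        cov = cov_df
    if cells is not None:
        pct = pct.reindex(index=sorted(cells))
        cov = cov.reindex(index=sorted(cells))
    if amplicons is not None:
        pct = pct.reindex(columns=list(amplicons))
        cov = cov.reindex(columns=list(amplicons))
    cov = cov.fillna(0).astype(int)
    return pct, cov


def quantify_bulk(reads, panel: Panel,
                  scoring: AlignmentScoring = DEFAULT_SCORING,
                  min_identity: float = 0.65,
                  min_reads: int = 1,
                  count_substitutions: bool = False) -> pd.DataFrame:
    """Bulk-mode quantification: the whole file is one pseudo-cell.

    ``reads`` is an iterable of raw amplicon sequences (strings) or
    ReadRecords without cell barcodes.  Returns a per-amplicon table of
    aligned reads, modified reads and percent modified (CRISPR amplicons
    only; controls report coverage with NaN percent).
    """
    per_amp: dict[str, list[int]] = {a.amplicon_id: [0, 0] for a in panel}
    cache: dict[str, tuple[Optional[str], Optional[bool]]] = {}
    for read in reads:
        seq = read if isinstance(read, str) else read.seq
        if seq in cache:
            amp_id, modified = cache[seq]
        else:
            assignment = assign_amplicon(seq, panel, scoring, min_identity)
            if assignment.amplicon_id is None:
                amp_id, modified = None, None
            else:
                amp_id = assignment.amplicon_id
                amp = panel[amp_id]
                modified = (classify_read(assignment.alignment, amp,
                                          count_substitutions)
                            if not amp.is_control else False)
            cache[seq] = (amp_id, modified)
        if amp_id is None:
            continue
        per_amp[amp_id][0] += 1
        if modified:
            per_amp[amp_id][1] += 1
    rows = []
    for amp in panel:
        n, n_mod = per_amp[amp.amplicon_id]
        if n == 0:
            continue
        pct = np.nan if amp.is_control or n < min_reads else 100.0 * n_mod / n
        rows.append({"amplicon_id": amp.amplicon_id, "category": amp.category,
                     "n_reads": n, "n_modified": n_mod, "pct_modified": pct})
    return pd.DataFrame(rows,
                        columns=["amplicon_id", "category", "n_reads",
                                 "n_modified", "pct_modified"])


def summaries_to_frame(summaries: Iterable[CellAmpliconSummary]) -> pd.DataFrame:
    """Flatten summaries to the per-cell-amplicon output table."""
    rows = []
    for s in summaries:
        rows.append({
            "barcode": s.barcode,
            "amplicon_id": s.amplicon_id,
            "n_reads": s.n_reads,
            "pct_modified": s.pct_modified,
            "heterozygosity": s.heterozygosity,
            "allele1_seq": s.allele1.allele_seq if s.allele1 else "",
            "allele1_modified": s.allele1.modified if s.allele1 else False,
            "allele1_freq": s.allele1.frequency if s.allele1 else 0.0,
            "allele2_seq": s.allele2.allele_seq if s.allele2 else "",
            "allele2_modified": s.allele2.modified if s.allele2 else False,
            "allele2_freq": s.allele2.frequency if s.allele2 else 0.0,
        })
    return pd.DataFrame(rows)
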