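"""End-to-end single-cell pipeline: reads -> per-cell edit calls.

Stages: barcode extraction and filtering, cell calling by read count,
per-read amplicon assignment and alignment, window-based modification
calling, per-(cell, amplicon) allele tabulation, and the compiled
modification-rate matrix with zygosity calls.

Amplicon assignment is memoized on the payload sequence: droplet
amplicon data is highly redundant (most reads are exact copies of a
small set of alleles), so the cache collapses the alignment workload by
one to two orders of magnitude without changing any result.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .align import DEFAULT_SCORING, AlignmentScoring, assign_amplicon
from .cells import DEFAULT_MIN_CELL_READS, call_cells, count_barcodes
from .panel import Panel
from .quantify import (ALLELE_FLANK, DEFAULT_MIN_AMPLICON_READS,
                       build_edit_matrix, classify_read, summaries_to_frame,
                       summarize_cell_amplicon, window_allele)
from .reads import FilterStats, ReadRecord, ReadStructure, filter_stream
from .zygosity import calls_from_summaries


@dataclass
class PipelineResult:
    """All outputs of one pipeline run."""

    filter_stats: FilterStats
    barcode_table: pd.DataFrame
    valid_barcodes: set
    summaries: list
    summary_table: pd.DataFrame
    edit_matrix: pd.DataFrame
    coverage: pd.DataFrame
    zygosity_calls: pd.DataFrame
    assignment_tally: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "filter_stats.json").write_text(self.filter_stats.to_json())
        self.barcode_table.to_csv(outdir / "cell_barcodes.tsv", sep="\t",
                                  index=False)
        self.summary_table.to_csv(outdir / "cell_amplicon_summary.tsv",
                                  sep="\t", index=False)
        self.edit_matrix.to_csv(outdir / "edit_matrix.tsv", sep="\t")
        self.coverage.to_csv(outdir / "coverage_matrix.tsv", sep="\t")
        self.zygosity_calls.to_csv(outdir / "zygosity_calls.tsv", sep="\t",
                                   index=False)
        self._write_mtx(outdir)

    def _write_mtx(self, outdir: Path) -> None:
        """Edit matrix as MatrixMarket with row/column index files."""
        import numpy as np
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix
        mat = self.edit_matrix.to_numpy(dtype=float)
        mask = ~np.isnan(mat)
        rows, cols = np.nonzero(mask)
        sparse = coo_matrix((mat[mask], (rows, cols)), shape=mat.shape)
        mmwrite(outdir / "edit_matrix.mtx", sparse)
        pd.Series(self.edit_matrix.index).to_csv(
            outdir / "edit_matrix.rows.tsv", sep="\t", index=False,
            header=["barcode"])
        pd.Series(self.edit_matrix.columns).to_csv(
            outdir / "edit_matrix.cols.tsv", sep="\t", index=False,
            header=["amplicon_id"])


def run_pipeline(reads: Iterable[ReadRecord],
                 panel: Panel,
                 structure: ReadStructure,
                 *,
                 min_cell_reads: int = DEFAULT_MIN_CELL_READS,
                 min_amplicon_reads: int = DEFAULT_MIN_AMPLICON_READS,
                 scoring: AlignmentScoring = DEFAULT_SCORING,
                 min_identity: float = 0.65,
                 count_substitutions: bool = False,
                 allele_flank: int = ALLELE_FLANK) -> PipelineResult:
    """Run the full single-cell edit-detection pipeline over a read stream."""
    tagged, stats = filter_stream(reads, structure)
    counts = count_barcodes(tagged)
    valid, barcode_table = call_cells(counts, min_reads=min_cell_reads)

    # per-read assignment + window call, memoized on payload sequence
    cache: dict[str, Optional[tuple[str, Optional[bool], str]]] = {}
    groups: dict[tuple[str, str], list[tuple[bool, str]]] = defaultdict(list)
    coverage_raw: dict[tuple[str, str], int] = defaultdict(int)
    tally = {"assigned": 0, "unassigned": 0, "control": 0}
    for t in tagged:
        if t.barcode not in valid:
            continue
        hit = cache.get(t.payload_seq, "MISS")
        if hit == "MISS":
            assignment = assign_amplicon(t.payload_seq, panel, scoring,
                                         min_identity)
            if assignment.amplicon_id is None:
                hit = None
            else:
                amp = panel[assignment.amplicon_id]
                if amp.is_control:
                    hit = (amp.amplicon_id, None, "")
                else:
                    modified = classify_read(assignment.alignment, amp,
                                             count_substitutions)
                    allele = window_allele(assignment.alignment, amp,
                                           assignment.oriented_seq,
                                           flank=allele_flank)
                    hit = (amp.amplicon_id, modified, allele)
            cache[t.payload_seq] = hit
        if hit is None:
            tally["unassigned"] += 1
            continue
        amp_id, modified, allele = hit
        coverage_raw[(t.barcode, amp_id)] += 1
        if modified is None:  # control amplicon: coverage only
            tally["control"] += 1
            continue
        tally["assigned"] += 1
        groups[(t.barcode, amp_id)].append((modified, allele))

    summaries = []
    for (bc, amp_id), calls in sorted(groups.items()):
        s = summarize_cell_amplicon(bc, amp_id, calls,
                                    min_reads=min_amplicon_reads)
        if s is not None:
            summaries.append(s)

    crispr_ids = [a.amplicon_id for a in panel if not a.is_control]
    if summaries:
        edit_matrix, coverage = build_edit_matrix(
            summaries, coverage=dict(coverage_raw) or None,
            cells=sorted(valid), amplicons=panel.ids)
        edit_matrix = edit_matrix[crispr_ids]
    else:
        edit_matrix = pd.DataFrame(index=sorted(valid), columns=crispr_ids,
                                   dtype=float)
        coverage = pd.DataFrame(0, index=sorted(valid), columns=panel.ids)
    zyg_calls = calls_from_summaries(summaries)

    return PipelineResult(
        filter_stats=stats,
        barcode_table=barcode_table,
        valid_barcodes=valid,
        summaries=summaries,
        summary_table=summaries_to_frame(summaries),
        edit_matrix=edit_matrix,
        coverage=coverage,
        zygosity_calls=zyg_calls,
        assignment_tally=tally,
    )
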