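"""Amplicon panel model.

An amplicon panel describes the targeted loci of a single-cell CRISPR
amplicon assay: for each amplicon its reference sequence, its category
(CRISPR on-target, putative off-target, or positive control), and — for
CRISPR amplicons — the guide geometry from which the predicted Cas9
cleavage site and the indel quantification window are derived.

Coordinate conventions
----------------------
All coordinates are 0-based.  The cut site is an *inter-base* index: Cas9
cleaves between reference positions ``cut_site - 1`` and ``cut_site``.
Quantification windows are half-open intervals ``[cut_site - w,
cut_site + w)`` of width ``2 w``; SpCas9 cleaves bluntly 3 bp 5' of the
PAM on the protospacer strand, which is the rule applied on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

from .seq import matches_pattern, revcomp

CATEGORIES = ("on_target", "off_target", "control")

DEFAULT_PAM = "NGG"
#: Distance (bp) of the blunt SpCas9 cut from the PAM-proximal end of the
#: protospacer.
CUT_OFFSET_FROM_PAM = 3


class PanelValidationError(ValueError):
    """Raised when a panel or amplicon violates its invariants."""


@dataclass
class Amplicon:
    """One targeted amplicon with optional guide geometry.

    For CRISPR amplicons (``on_target``/``off_target``) the guide spacer
    must occur in ``ref_seq`` (forward strand) or its reverse complement
    (reverse strand) immediately adjacent to a PAM.  Control amplicons
    carry no guide, no cut site and no quantification window.
    """

    amplicon_id: str
    ref_seq: str
    category: str
    guide_spacer: Optional[str] = None
    guide_strand: Optional[str] = None
    pam_start: Optional[int] = None
    cut_site: Optional[int] = None
    window_halfwidth: int = 2

    def __post_init__(self) -> None:
        self.ref_seq = self.ref_seq.upper()
        if self.guide_spacer is not None:
            self.guide_spacer = self.guide_spacer.upper()
        if self.category not in CATEGORIES:
            raise PanelValidationError(
                f"{self.amplicon_id}: unknown category {self.category!r}"
            )
        if self.category != "control":
            if not self.guide_spacer:
                raise PanelValidationError(
                    f"{self.amplicon_id}: CRISPR amplicon requires a guide_spacer"
                )
            if self.guide_strand not in ("forward", "reverse"):
                raise PanelValidationError(
                    f"{self.amplicon_id}: guide_strand must be forward/reverse"
                )
            if len(self.ref_seq) < 40:
                raise PanelValidationError(
                    f"{self.amplicon_id}: CRISPR amplicon reference shorter "
                    f"than 40 bp ({len(self.ref_seq)})"
                )

    @property
    def is_control(self) -> bool:
        return self.category == "control"

    @property
    def window(self) -> Optional[tuple[int, int]]:
        """Half-open quantification window, or None for controls."""
        if self.cut_site is None:
            return None
        return (self.cut_site - self.window_halfwidth,
                self.cut_site + self.window_halfwidth)

    def validate_window(self) -> None:
        if self.cut_site is None:
            return
        lo, hi = self.window
        if not (0 <= self.cut_site <= len(self.ref_seq)):
            raise PanelValidationError(
                f"{self.amplicon_id}: cut_site {self.cut_site} outside reference"
            )
        if lo < 0 or hi > len(self.ref_seq):
            raise PanelValidationError(
                f"{self.amplicon_id}: quantification window [{lo}, {hi}) "
                f"outside reference of length {len(self.ref_seq)}"
            )


def locate_guide(amplicon: Amplicon, pam: str = DEFAULT_PAM) -> tuple[int, int]:
    """Locate the guide on the reference and return ``(pam_start, cut_site)``.

    The spacer is searched on the strand declared by ``guide_strand``; a
    valid placement requires the PAM immediately 3' of the spacer on that
    strand.  Exactly one placement must exist.
    """
    ref = amplicon.ref_seq
    spacer = amplicon.guide_spacer
    if not spacer:
        raise PanelValidationError(f"{amplicon.amplicon_id}: no guide to locate")
    plen = len(pam)
    hits: list[tuple[int, int]] = []
    if amplicon.guide_strand == "forward":
        start = ref.find(spacer)
        while start != -1:
            p = start + len(spacer)
            if p + plen <= len(ref) and matches_pattern(ref[p:p + plen], pam):
                # blunt cut CUT_OFFSET_FROM_PAM bases 5' of the PAM
                hits.append((p, p - CUT_OFFSET_FROM_PAM))
            start = ref.find(spacer, start + 1)
    else:
        target = revcomp(spacer)
        pam_rc = revcomp(pam)
        start = ref.find(target)
        while start != -1:
            s = start - plen  # reverse-complemented PAM occupies [s, start)
            if s >= 0 and matches_pattern(ref[s:start], pam_rc):
                q = start - 1  # 0-based inclusive end of the PAM on ref
                hits.append((s, q + CUT_OFFSET_FROM_PAM + 1))
            start = ref.find(target, start + 1)
    if not hits:
        raise PanelValidationError(
            f"{amplicon.amplicon_id}: guide spacer with adjacent {pam} PAM "
            f"not found on the {amplicon.guide_strand} strand"
        )
    if len(hits) > 1:
        raise PanelValidationError(
            f"{amplicon.amplicon_id}: guide placement ambiguous ({len(hits)} hits)"
        )
    return hits[0]


def compute_cut_site(amplicon: Amplicon, pam: str = DEFAULT_PAM) -> int:
    """Compute and store the inter-base cut site for a CRISPR amplicon.

    Also validates that the quantification window fits the reference.
    """
    pam_start, cut = locate_guide(amplicon, pam=pam)
    amplicon.pam_start = pam_start
    amplicon.cut_site = cut
    amplicon.validate_window()
    return cut


@dataclass
class Panel:
    """Ordered collection of amplicons with unique ids."""

    amplicons: list[Amplicon] = field(default_factory=list)
    name: str = "panel"

    def __post_init__(self) -> None:
        if not self.amplicons:
            raise PanelValidationError("panel must contain at least one amplicon")
        ids = [a.amplicon_id for a in self.amplicons]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PanelValidationError(f"duplicate amplicon ids: {sorted(dupes)}")
        self._by_id = {a.amplicon_id: a for a in self.amplicons}

    def __iter__(self) -> Iterator[Amplicon]:
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)

    def __getitem__(self, amplicon_id: str) -> Amplicon:
        return self._by_id[amplicon_id]

    def __contains__(self, amplicon_id: str) -> bool:
        return amplicon_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [a.amplicon_id for a in self.amplicons]

    @property
    def on_targets(self) -> list[str]:
        return [a.amplicon_id for a in self.amplicons if a.category == "on_target"]

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for a in self.amplicons:
            counts[a.category] += 1
        return counts


def load_panel(path: str | Path, name: Optional[str] = None,
               pam: str = DEFAULT_PAM) -> Panel:
    """Load a panel from a TSV file and compute cut sites/windows.

    Required columns: ``amplicon_id``, ``ref_seq``, ``category``; CRISPR
    amplicons additionally need ``guide_spacer`` and ``guide_strand``.
    An optional ``window_halfwidth`` column overrides the default of 2.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"amplicon_id", "ref_seq", "category"}
    missing = required - set(df.columns)
    if missing:
        raise PanelValidationError(f"panel file missing columns: {sorted(missing)}")
    amplicons = []
    for _, row in df.iterrows():
        halfwidth = int(row["window_halfwidth"]) if row.get("window_halfwidth") else 2
        amp = Amplicon(
            amplicon_id=row["amplicon_id"],
            ref_seq=row["ref_seq"],
            category=row["category"],
            guide_spacer=row.get("guide_spacer") or None,
            guide_strand=row.get("guide_strand") or None,
            window_halfwidth=halfwidth,
        )
        if not amp.is_control:
            compute_cut_site(amp, pam=pam)
        amplicons.append(amp)
    return Panel(amplicons=amplicons, name=name or path.stem)


def write_panel(panel: Panel, path: str | Path) -> None:
    """Write a panel back to the TSV interchange format."""
    rows = [
        {
            "amplicon_id": a.amplicon_id,
            "ref_seq": a.ref_seq,
            "category": a.category,
            "guide_spacer": a.guide_spacer or "",
            "guide_strand": a.guide_strand or "",
            "window_halfwidth": a.window_halfwidth,
        }
        for a in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
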