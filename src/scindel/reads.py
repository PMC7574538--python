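"""Raw read handling: barcode extraction, trimming, filtering, pair merging.

The droplet library places two 9-nt cell barcodes between three constant
segments at the 5' end of each (merged) read::

    constant_1 | barcode_1 (9 nt) | constant_2 | barcode_2 (9 nt) | constant_3 | amplicon payload

Extraction removes the constants, concatenates the two barcode halves
into an 18-nt composite cell barcode, and keeps the remaining payload.
Reads whose payload is shorter than 46 bp, or whose composite barcode is
shorter than 18 bp, are discarded and tallied.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seq import revcomp

MIN_PAYLOAD_LEN = 46
MIN_BARCODE_LEN = 18

DISCARD_REASONS = ("short_read", "short_barcode", "structure_not_found")


@dataclass
class ReadRecord:
    """A raw sequencing read; quality is optional (simulated data may omit it)."""

    read_id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"{self.read_id}: quality/sequence length mismatch")


@dataclass
class TaggedRead:
    """A read with its extracted composite cell barcode and trimmed payload."""

    read_id: str
    barcode: str
    payload_seq: str


@dataclass
class Discard:
    """Outcome for a read rejected during extraction."""

    reason: str

    def __post_init__(self) -> None:
        if self.reason not in DISCARD_REASONS:
            raise ValueError(f"unknown discard reason {self.reason!r}")


@dataclass
class ReadStructure:
    """Layout of the constant segments and barcodes at the read 5' end."""

    constant_1: str
    constant_2: str
    constant_3: str
    barcode_len: int = 9
    max_constant_mismatches: int = 0

    def __post_init__(self) -> None:
        if not (self.constant_1 and self.constant_2 and self.constant_3):
            raise ValueError("constant segments must be non-empty")
        if self.barcode_len < 1:
            raise ValueError("barcode_len must be >= 1")

    @property
    def prefix_len(self) -> int:
        """Total length of constants plus both barcodes."""
        return (len(self.constant_1) + len(self.constant_2) + len(self.constant_3)
                + 2 * self.barcode_len)


@dataclass
class FilterStats:
    """Tally of read fates for one filtering run."""

    n_input: int = 0
    n_retained: int = 0
    discards: dict = field(default_factory=lambda: {r: 0 for r in DISCARD_REASONS})

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input, "n_retained": self.n_retained,
             "discards": self.discards}, indent=2)


def _segment_matches(seq: str, expected: str, max_mm: int) -> bool:
    if len(seq) != len(expected):
        return False
    if max_mm == 0:
        return seq == expected
    mm = 0
    for a, b in zip(seq, expected):
        if a != b:
            mm += 1
            if mm > max_mm:
                return False
    return True


def extract_and_trim(read: ReadRecord,
                     structure: ReadStructure) -> Union[TaggedRead, Discard]:
    """Extract the composite barcode and trim constants from one read.

    Pure per-read function.  All failures are ``Discard`` outcomes with a
    reason; nothing raises on malformed biology.
    """
    s = read.seq
    bl = structure.barcode_len
    c1, c2, c3 = structure.constant_1, structure.constant_2, structure.constant_3
    mm = structure.max_constant_mismatches

    if len(s) < structure.prefix_len:
        # Too short to even hold the barcode scaffold: decide between a
        # truncated barcode and a broken structure.
        if len(s) >= len(c1) and _segment_matches(s[:len(c1)], c1, mm):
            return Discard("short_barcode")
        return Discard("structure_not_found")

    if not _segment_matches(s[:len(c1)], c1, mm):
        return Discard("structure_not_found")
    pos = len(c1)
    bc1 = s[pos:pos + bl]
    pos += bl
    if not _segment_matches(s[pos:pos + len(c2)], c2, mm):
        return Discard("structure_not_found")
    pos += len(c2)
    bc2 = s[pos:pos + bl]
    pos += bl
    if not _segment_matches(s[pos:pos + len(c3)], c3, mm):
        return Discard("structure_not_found")
    pos += len(c3)

    barcode = bc1 + bc2
    payload = s[pos:]
    if len(barcode) < MIN_BARCODE_LEN:
        return Discard("short_barcode")
    if len(payload) < MIN_PAYLOAD_LEN:
        return Discard("short_read")
    return TaggedRead(read_id=read.read_id, barcode=barcode, payload_seq=payload)


def merge_pair(r1: ReadRecord, r2: ReadRecord, min_overlap: int = 10,
               max_mismatch_frac: float = 0.1) -> ReadRecord:
    """Merge a read pair into a single read.

    ``r2`` is reverse-complemented, then the longest 3'(r1)/5'(rc-r2)
    overlap of at least ``min_overlap`` bases with a mismatch fraction at
    most ``max_mismatch_frac`` is used; conflicting bases are resolved in
    favour of the higher base quality (r1 wins ties).  If no acceptable
    overlap exists the pair is force-merged by concatenation.
    """
    rc2 = revcomp(r2.seq)
    q2 = r2.qual[::-1] if r2.qual is not None else None
    best = None
    for ov in range(min(len(r1.seq), len(rc2)), min_overlap - 1, -1):
        a = r1.seq[len(r1.seq) - ov:]
        b = rc2[:ov]
        mism = sum(x != y for x, y in zip(a, b))
        if mism <= max_mismatch_frac * ov:
            best = ov
            break
    if best is None:
        seq = r1.seq + rc2
        qual = (r1.qual + q2) if (r1.qual is not None and q2 is not None) else None
        return ReadRecord(read_id=r1.read_id, seq=seq, qual=qual)

    ov = best
    head = r1.seq[:len(r1.seq) - ov]
    tail = rc2[ov:]
    mid = []
    midq = []
    for k in range(ov):
        b1 = r1.seq[len(r1.seq) - ov + k]
        b2 = rc2[k]
        q1c = r1.qual[len(r1.seq) - ov + k] if r1.qual is not None else "!"
        q2c = q2[k] if q2 is not None else "!"
        if b1 == b2 or q1c >= q2c:
            mid.append(b1)
            midq.append(max(q1c, q2c) if b1 == b2 else q1c)
        else:
            mid.append(b2)
            midq.append(q2c)
    seq = head + "".join(mid) + tail
    if r1.qual is not None and q2 is not None:
        qual = r1.qual[:len(r1.seq) - ov] + "".join(midq) + q2[ov:]
    else:
        qual = None
    return ReadRecord(read_id=r1.read_id, seq=seq, qual=qual)


def filter_stream(reads: Iterable[ReadRecord], structure: ReadStructure,
                  ) -> tuple[list[TaggedRead], FilterStats]:
    """Run extraction over a read stream and tally every fate.

    Conservation holds by construction: ``n_input == n_retained +
    sum(discards.values())``.
    """
    stats = FilterStats()
    tagged: list[TaggedRead] = []
    for read in reads:
        stats.n_input += 1
        out = extract_and_trim(read, structure)
        if isinstance(out, TaggedRead):
            stats.n_retained += 1
            tagged.append(out)
        else:
            stats.discards[out.reason] += 1
    return tagged, stats


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FASTQ file (gzip transparently handled)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        idx = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                yield ReadRecord(read_id=title.split()[0], seq=seq, qual=qual)
                idx += 1
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            handle.write(f"@{r.read_id}\n{r.seq}\n+\n{qual}\n")


def write_tagged_fastq(tagged: Iterable[TaggedRead], path: str | Path,
                       delimiter: str = ":BC:") -> None:
    """Serialize tagged reads with the barcode appended to the read name."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for t in tagged:
            handle.write(f"@{t.read_id}{delimiter}{t.barcode}\n"
                         f"{t.payload_seq}\n+\n{'I' * len(t.payload_seq)}\n")
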