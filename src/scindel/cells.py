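"""Cell calling: identify valid cell barcodes by total tagged-read count.

The assay uses a fixed read-count cutoff rather than a knee-point rule;
the default of 1000 reads corresponds to a ~28-amplicon panel and should
be scaled with panel size and desired depth.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import pandas as pd

from .reads import TaggedRead

DEFAULT_MIN_CELL_READS = 1000


def count_barcodes(tagged: Iterable[TaggedRead]) -> Counter:
    """Tally tagged reads per composite cell barcode."""
    return Counter(t.barcode for t in tagged)


def call_cells(counts: Mapping[str, int],
               min_reads: int = DEFAULT_MIN_CELL_READS,
               ) -> tuple[set, pd.DataFrame]:
    """Return the set of valid barcodes and a per-barcode pass/fail table.

    A barcode is retained iff its read count is >= ``min_reads``
    (inclusive threshold).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    table = pd.DataFrame(
        {"barcode": list(counts.keys()),
         "read_count": list(counts.values())}
    ).sort_values(["read_count", "barcode"], ascending=[False, True],
                  ignore_index=True)
    table["pass"] = table["read_count"] >= min_reads
    valid = set(table.loc[table["pass"], "barcode"])
    return valid, table
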