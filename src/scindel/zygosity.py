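"""Zygosity classification from modification rate and heterozygosity.

Per cell and amplicon, with ``pct_modified`` the percentage of modified
reads and ``heterozygosity`` the frequency (in percent) of the
second-most-frequent allele:

* ``pct_modified < lower``                              -> WT/WT
* ``lower <= pct_modified < upper``                     -> WT/Mut
* ``pct_modified >= upper`` and ``het >= lower``        -> Mut/Mut2
* ``pct_modified >= upper`` and ``het < lower``         -> Mut/Mut

with defaults ``lower = 20`` and ``upper = 80``.  A true heterozygote
has both rates near 50%; a homozygote for a single edited allele has a
high modification rate but near-zero heterozygosity; a compound
heterozygote (two distinct edited alleles) has both high.
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

WT_WT = "WT/WT"
WT_MUT = "WT/Mut"
MUT_MUT2 = "Mut/Mut2"
MUT_MUT = "Mut/Mut"
NO_CALL = "NO_CALL"

CLASSES = (WT_WT, WT_MUT, MUT_MUT2, MUT_MUT)

DEFAULT_LOWER = 20.0
DEFAULT_UPPER = 80.0


def classify_zygosity(pct_modified: float, heterozygosity: float,
                      lower: float = DEFAULT_LOWER,
                      upper: float = DEFAULT_UPPER) -> str:
    """Classify one called cell-amplicon into the four zygosity classes."""
    if not (0 <= pct_modified <= 100) or not (0 <= heterozygosity <= 100):
        raise ValueError("pct_modified and heterozygosity must be in [0, 100]")
    if pct_modified < lower:
        return WT_WT
    if pct_modified < upper:
        return WT_MUT
    if heterozygosity >= lower:
        return MUT_MUT2
    return MUT_MUT


def calls_from_summaries(summaries: Iterable,
                         lower: float = DEFAULT_LOWER,
                         upper: float = DEFAULT_UPPER) -> pd.DataFrame:
    """Zygosity-call table from CellAmpliconSummary objects."""
    rows = []
    for s in summaries:
        rows.append({
            "barcode": s.barcode,
            "amplicon_id": s.amplicon_id,
            "pct_modified": s.pct_modified,
            "heterozygosity": s.heterozygosity,
            "zygosity": classify_zygosity(s.pct_modified, s.heterozygosity,
                                          lower, upper),
        })
    return pd.DataFrame(rows, columns=["barcode", "amplicon_id", "pct_modified",
                                       "heterozygosity", "zygosity"])


def zygosity_composition(calls: Iterable[str]) -> dict:
    """Fractions over the four classes, plus the edited-only renormalization
    (WT/WT omitted), over called cells.

    ``calls`` may contain NO_CALL entries; they are excluded from both
    denominators.  All-NO_CALL input yields empty compositions.
    """
    called = [c for c in calls if c != NO_CALL]
    out: dict = {"n_called": len(called), "fractions": {}, "edited_only": {}}
    if not called:
        return out
    n = len(called)
    counts = {cls: called.count(cls) for cls in CLASSES}
    out["fractions"] = {cls: counts[cls] / n for cls in CLASSES}
    n_edited = n - counts[WT_WT]
    if n_edited:
        out["edited_only"] = {cls: counts[cls] / n_edited
                              for cls in CLASSES if cls != WT_WT}
    return out
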