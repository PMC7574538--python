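"""Cell-level multi-target summaries.

Edited-target counts per cell, doublet flagging for admixture designs
(where each true cell carries at most one edited target, so multi-target
editing betrays a droplet multiplet), per-gene edited fractions among
covered cells, and combinatorial-assortment (upset-style) tables.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_EDIT_THRESHOLD = 20.0
DEFAULT_COVERAGE_MIN = 5


def count_edited_targets(edit_matrix: pd.DataFrame,
                         on_targets: Sequence[str],
                         edit_threshold: float = DEFAULT_EDIT_THRESHOLD,
                         ) -> pd.DataFrame:
    """Per-cell edited flags over the on-target loci.

    A target is edited when called (non-missing) and ``pct_modified >=
    edit_threshold``; missing (insufficient-coverage) targets count as
    unedited for the flags, but ``n_covered`` reports how many targets
    were actually called so downstream users can filter.
    """
    missing = [t for t in on_targets if t not in edit_matrix.columns]
    if missing:
        raise KeyError(f"on-targets not in matrix: {missing}")
    sub = edit_matrix[list(on_targets)]
    flags = (sub >= edit_threshold).fillna(False).astype(bool)
    profile = flags.copy()
    profile["n_edited"] = flags.sum(axis=1)
    profile["n_covered"] = sub.notna().sum(axis=1)
    return profile


def flag_doublets_admixture(profiles: pd.DataFrame) -> dict:
    """Flag admixture barcodes edited at two or more on-target sites.

    Only meaningful for admixture designs; in a multiplexed line,
    multi-edited cells are biology, not artifacts.  Returns a report
    with counts of two-edit and more-than-two-edit barcodes and the
    flagged rate, plus the per-cell flags.
    """
    n_edited = profiles["n_edited"]
    flags = n_edited >= 2
    n = len(profiles)
    n_two = int((n_edited == 2).sum())
    n_more = int((n_edited > 2).sum())
    return {
        "n_cells": n,
        "n_two_edits": n_two,
        "n_more_than_two": n_more,
        "n_flagged": n_two + n_more,
        "doublet_rate": (n_two + n_more) / n if n else float("nan"),
        "flags": flags,
    }


def per_gene_edited_fraction(edit_matrix: pd.DataFrame,
                             coverage: pd.DataFrame,
                             on_targets: Sequence[str],
                             coverage_min: int = DEFAULT_COVERAGE_MIN,
                             edit_threshold: float = DEFAULT_EDIT_THRESHOLD,
                             ) -> pd.DataFrame:
    """Edited / covered cell counts and fraction per on-target gene.

    Denominator: cells with at least ``coverage_min`` reads on the
    amplicon; numerator: those at or above the edit threshold.  The
    fraction is NaN when no cell is covered.
    """
    rows = []
    for gene in on_targets:
        cov_ok = coverage[gene].reindex(edit_matrix.index).fillna(0) >= coverage_min
        covered = int(cov_ok.sum())
        edited = int(((edit_matrix[gene] >= edit_threshold) & cov_ok).sum())
        frac = edited / covered if covered else np.nan
        rows.append({"gene": gene, "edited": edited, "covered": covered,
                     "fraction": frac})
    return pd.DataFrame(rows, columns=["gene", "edited", "covered", "fraction"])


def multiplicity_histogram(profiles: pd.DataFrame,
                           n_targets: Optional[int] = None) -> pd.Series:
    """Histogram of the number of edited targets per cell (0..n_targets)."""
    if n_targets is None:
        n_targets = len([c for c in profiles.columns
                         if c not in ("n_edited", "n_covered")])
    counts = profiles["n_edited"].value_counts()
    return counts.reindex(range(n_targets + 1), fill_value=0).sort_index()


def combination_counts(profiles: pd.DataFrame,
                       on_targets: Sequence[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Exact-subset intersection counts plus per-gene marginal set sizes.

    For each observed subset S of edited targets the intersection size
    is the number of cells whose edited set equals S exactly; the set
    size of gene g is the number of cells edited at g (equivalently the
    sum of intersection sizes over subsets containing g).
    """
    flags = profiles[list(on_targets)].astype(bool)
    subsets = Counter(
        tuple(g for g, f in zip(on_targets, row) if f)
        for row in flags.itertuples(index=False)
    )
    table = pd.DataFrame(
        [{"subset": "+".join(s) if s else "(none)",
          "degree": len(s),
          "intersection_size": c}
         for s, c in subsets.items()]
    ).sort_values(["degree", "subset"], ignore_index=True)
    marginals = flags.sum(axis=0)
    marginals.name = "set_size"
    return table, marginals
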