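"""Per-cell sgRNA presence calling from a Fluidigm-style Cq matrix.

Each cell is assayed for each sgRNA with several qPCR replicates (8 by
default on a 96.96 array with 12 assays).  An sgRNA is called present
in a cell when at least ``min_positive_reps`` replicates amplify at or
below ``cq_max`` cycles.  A count-of-positives rule is used instead of
a median Cq because single-cell qPCR is dropout-prone and the
no-amplification sentinel makes medians unstable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

#: Thermal protocol runs 30 PCR cycles; valid Cq values cannot exceed it.
MAX_CYCLES = 30

DEFAULT_CQ_MAX = 25.0
DEFAULT_MIN_POSITIVE_REPS = 4
DEFAULT_NO_AMP_TOKEN = "999"


def load_cq_long(path: str | Path,
                 no_amp_token: str = DEFAULT_NO_AMP_TOKEN) -> pd.DataFrame:
    """Load a long-format Cq table (columns: cell, assay, replicate, cq).

    The no-amplification sentinel becomes NaN.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "assay": str})
    required = {"cell", "assay", "replicate", "cq"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Cq table missing columns: {sorted(missing)}")
    df = df.copy()
    num = pd.to_numeric(df["cq"], errors="coerce")
    sentinel = df["cq"].astype(str).str.strip() == no_amp_token
    try:
        sentinel |= num == float(no_amp_token)
    except ValueError:
        pass
    df["cq"] = num.mask(sentinel)
    validate_cq(df)
    return df


def validate_cq(df: pd.DataFrame) -> None:
    vals = df["cq"].dropna()
    if ((vals <= 0) | (vals > MAX_CYCLES)).any():
        raise ValueError(f"Cq values must lie in (0, {MAX_CYCLES}]")


def call_presence(cq: pd.DataFrame,
                  cq_max: float = DEFAULT_CQ_MAX,
                  min_positive_reps: int = DEFAULT_MIN_POSITIVE_REPS,
                  assay_map: Optional[Mapping[str, str]] = None,
                  ) -> dict:
    """Call per-cell sgRNA presence and summarize multiplicity/co-occurrence.

    ``cq`` is the long-format table from :func:`load_cq_long` (NaN =
    no amplification).  ``assay_map`` optionally renames assay ids to
    sgRNA names; unknown assay ids raise.

    Returns a dict with the boolean presence matrix (cells x sgRNAs),
    the per-cell multiplicity, the multiplicity histogram and the
    pairwise co-occurrence count matrix.
    """
    if not (0 < cq_max <= MAX_CYCLES):
        raise ValueError(f"cq_max must lie in (0, {MAX_CYCLES}]")
    df = cq.copy()
    if assay_map is not None:
        unknown = set(df["assay"].unique()) - set(assay_map)
        if unknown:
            raise KeyError(f"unknown assay ids: {sorted(unknown)}")
        df["assay"] = df["assay"].map(assay_map)
    positive = df["cq"].notna() & (df["cq"] <= cq_max)
    pos_counts = (
        df.assign(positive=positive)
        .groupby(["cell", "assay"], sort=True)["positive"].sum()
        .unstack("assay", fill_value=0)
    )
    presence = pos_counts >= min_positive_reps
    multiplicity = presence.sum(axis=1)
    n_assays = presence.shape[1]
    histogram = (multiplicity.value_counts()
                 .reindex(range(n_assays + 1), fill_value=0).sort_index())
    pres_int = presence.astype(int)
    cooccurrence = pres_int.T @ pres_int
    np.fill_diagonal(cooccurrence.values, pres_int.sum(axis=0))
    return {
        "presence": presence,
        "multiplicity": multiplicity,
        "histogram": histogram,
        "cooccurrence": cooccurrence,
    }
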