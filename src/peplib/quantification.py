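"""NSAF relative abundance from spectral counts.

For each protein i within a cell type, saf_i = spectral_count_i /
length_i and nsaf_i = saf_i / sum_j saf_j, so nsaf is a proportion
summing to 1 per cell type. Counts are consumed as already aggregated
per protein group by the upstream search; no razor-peptide
apportionment is performed here.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from .proteome_io import ProteinRecord

COUNT_COLUMNS = ("cell_type", "accession", "spectral_count")


def compute_nsaf(
    counts: pd.DataFrame, proteins: Sequence[ProteinRecord]
) -> pd.DataFrame:
    """NSAF table from a (cell_type, accession, spectral_count) table.

    Zero-count rows are retained with nsaf 0 so cross-cell-type matrices
    align. Raises on accessions absent from the proteome, duplicated
    (cell_type, accession) rows, negative counts, or a cell type with no
    positive count.
    """
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"spectral-count table lacks columns: {missing}")
    lengths = {p.accession: p.length for p in proteins}
    unknown = sorted(set(counts["accession"]) - set(lengths))
    if unknown:
        raise ValueError(f"accessions not in proteome: {unknown}")
    if counts.duplicated(["cell_type", "accession"]).any():
        dup = counts[counts.duplicated(["cell_type", "accession"])].iloc[0]
        raise ValueError(
            f"duplicate row for ({dup['cell_type']}, {dup['accession']})"
        )
    if (counts["spectral_count"] < 0).any():
        raise ValueError("negative spectral counts")

    out = counts.copy()
    out["length"] = out["accession"].map(lengths)
    out["saf"] = out["spectral_count"] / out["length"]
    totals = out.groupby("cell_type")["saf"].transform("sum")
    zero_types = sorted(out.loc[totals == 0, "cell_type"].unique())
    if zero_types:
        raise ValueError(f"cell types with all-zero counts: {zero_types}")
    out["nsaf"] = out["saf"] / totals
    out = out.drop(columns=["length"]).sort_values(
        ["cell_type", "accession"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def dynamic_range(nsaf: pd.DataFrame, cell_type: str) -> float:
    """Orders of magnitude spanned by positive nsaf in one cell type."""
    sub = nsaf.loc[(nsaf["cell_type"] == cell_type) & (nsaf["nsaf"] > 0), "nsaf"]
    if len(sub) < 2:
        raise ValueError(
            f"need >= 2 positive nsaf entries for {cell_type!r}, got {len(sub)}"
        )
    return math.log10(sub.max() / sub.min())


def abundance_ranks(nsaf: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type rank (1 = most abundant), ties broken by accession."""
    out = nsaf.sort_values(
        ["cell_type", "nsaf", "accession"],
        ascending=[True, False, True],
        kind="mergesort",
    ).copy()
    out["rank"] = out.groupby("cell_type").cumcount() + 1
    return out.reset_index(drop=True)


def nsaf_matrix(nsaf: pd.DataFrame) -> pd.DataFrame:
    """Pivot to a proteins x cell-types matrix (missing -> 0)."""
    return (
        nsaf.pivot(index="accession", columns="cell_type", values="nsaf")
        .fillna(0.0)
        .sort_index()
    )
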