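"""Cell-type library assembly, set intersections and marker clustering.

Builds per-cell-type library tables (protein, peptide and PTM views),
computes exclusive (upset-style) intersection counts over the cell-type
protein sets, extracts cell-type-unique markers, and hierarchically
clusters marker abundance profiles (protein-wise min-max scaling,
Euclidean distance, complete linkage).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

from .digestion import (
    DEFAULT_CHARGES,
    DigestParams,
    count_missed_cleavages,
    peptide_mz,
)
from .proteome_io import ProteinRecord
from .proteotypicity import ProteotypicityIndex
from .ptm_annotation import PtmRecord, project_sites, sites_table
from .quantification import compute_nsaf
from .scoring import score_peptide, score_table


@dataclass
class CellTypeLibrary:
    cell_type: str
    proteins: pd.DataFrame  # accession, description, gene_symbol, n_proteotypic_peptides, nsaf, annotations
    peptides: pd.DataFrame  # accession, sequence, mz_z2..4, missed_cleavages, c1..c10, total
    ptm_sites: pd.DataFrame  # projected site annotations


@dataclass(frozen=True)
class IntersectionSummary:
    """Exclusive protein counts for every non-empty cell-type subset."""

    cell_types: tuple[str, ...]
    counts: dict[tuple[str, ...], int]

    @property
    def core(self) -> int:
        """Proteins present in every cell type."""
        return self.counts.get(self.cell_types, 0)

    def unique(self, cell_type: str) -> int:
        """Proteins present in exactly this cell type."""
        return self.counts.get((cell_type,), 0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative complete-linkage clustering of scaled profiles.

    ``merges`` lists (cluster_a, cluster_b, height) triples; leaves are
    labelled 0..n-1 in input row order, merge i creates cluster n+i.
    """

    labels: tuple[str, ...]
    scaled: pd.DataFrame
    merges: tuple[tuple[int, int, float], ...]
    leaf_order: tuple[str, ...]


def presence_sets(
    evidence: pd.DataFrame,
    index: ProteotypicityIndex,
    min_proteotypic_peptides: int = 1,
) -> dict[str, set[str]]:
    """Protein presence per cell type from peptide evidence.

    A protein is present in a cell type when at least
    ``min_proteotypic_peptides`` distinct proteotypic peptides mapping to
    it were observed there.
    """
    sets: dict[str, dict[str, set[str]]] = {}
    for row in evidence.itertuples(index=False):
        parents = index.parents_of(row.peptide)
        if len(parents) == 1 and parents[0] == row.accession:
            sets.setdefault(row.cell_type, {}).setdefault(
                row.accession, set()
            ).add(row.peptide)
    return {
        ct: {acc for acc, peps in accs.items()
             if len(peps) >= min_proteotypic_peptides}
        for ct, accs in sets.items()
    }


def build_libraries(
    counts: pd.DataFrame,
    evidence: pd.DataFrame,
    kept_ptms: Sequence[PtmRecord],
    proteome: Sequence[ProteinRecord],
    index: ProteotypicityIndex,
    annotations: Mapping[str, Sequence[str]] | None = None,
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> dict[str, CellTypeLibrary]:
    """Assemble one :class:`CellTypeLibrary` per cell type.

    ``evidence`` rows are (cell_type, peptide, accession) observations;
    peptide scores take c1 = observed in this cell type and c2 from the
    index. NSAF comes from the spectral-count table; missing annotation
    terms yield an empty column, not an error.
    """
    proteins_by_acc = {p.accession: p for p in proteome}
    unknown = sorted(set(evidence["accession"]) - set(proteins_by_acc))
    if unknown:
        raise ValueError(f"evidence references unknown accessions: {unknown}")
    annotations = annotations or {}
    nsaf = compute_nsaf(counts, proteome)
    nsaf_lookup = {
        (r.cell_type, r.accession): r.nsaf for r in nsaf.itertuples(index=False)
    }
    ptms_by_cell: dict[str, list[PtmRecord]] = {}
    for r in kept_ptms:
        ptms_by_cell.setdefault(r.cell_type, []).append(r)

    libraries: dict[str, CellTypeLibrary] = {}
    for cell_type, cell_ev in evidence.groupby("cell_type", sort=True):
        cell_ev = cell_ev.drop_duplicates(["peptide", "accession"]).sort_values(
            ["accession", "peptide"], kind="mergesort"
        )
        observed = set(cell_ev["peptide"])
        n_proteotypic: dict[str, int] = {}
        pep_rows, breakdowns, pep_accs = [], [], []
        for row in cell_ev.itertuples(index=False):
            parents = index.parents_of(row.peptide)
            proteotypic = len(parents) == 1 and parents[0] == row.accession
            if proteotypic:
                n_proteotypic[row.accession] = n_proteotypic.get(row.accession, 0) + 1
            mc = count_missed_cleavages(
                row.peptide, index.digest_params.cleave_before_proline
            )
            b = score_peptide(
                row.peptide,
                in_library=row.peptide in observed,
                proteotypic=proteotypic,
                missed_cleavages=mc,
            )
            breakdowns.append(b)
            pep_accs.append(row.accession)
            pep_row = {
                "accession": row.accession,
                "sequence": row.peptide,
                "missed_cleavages": mc,
            }
            for z in charges:
                pep_row[f"mz_z{z}"] = round(peptide_mz(row.peptide, z), 5)
            pep_rows.append(pep_row)

        peptides = pd.DataFrame(pep_rows)
        scores = score_table(breakdowns, accessions=pep_accs)
        peptides = pd.concat(
            [peptides, scores.drop(columns=["accession", "sequence"])], axis=1
        )

        accs = sorted(set(cell_ev["accession"]))
        prot_rows = []
        for acc in accs:
            p = proteins_by_acc[acc]
            prot_rows.append({
                "accession": acc,
                "description": p.description,
                "gene_symbol": p.gene_symbol,
                "n_proteotypic_peptides": n_proteotypic.get(acc, 0),
                "nsaf": nsaf_lookup.get((cell_type, acc), 0.0),
                "annotations": ";".join(annotations.get(acc, [])),
            })

        cell_ptms = ptms_by_cell.get(cell_type, [])
        site_frames = []
        for acc in accs:
            recs = [r for r in cell_ptms if r.accession == acc]
            if recs:
                site_frames.append(
                    sites_table(project_sites(proteins_by_acc[acc], recs))
                )
        ptm_sites = (
            pd.concat(site_frames, ignore_index=True)
            if site_frames
            else sites_table([])
        )
        libraries[str(cell_type)] = CellTypeLibrary(
            cell_type=str(cell_type),
            proteins=pd.DataFrame(prot_rows),
            peptides=peptides.reset_index(drop=True),
            ptm_sites=ptm_sites,
        )
    return libraries


def intersection_counts(sets: Mapping[str, set[str]]) -> IntersectionSummary:
    """Exclusive (upset-style) counts over all 2^k - 1 cell-type subsets."""
    if not sets:
        raise ValueError("need at least one cell-type set")
    cell_types = tuple(sets.keys())
    membership: dict[str, tuple[str, ...]] = {}
    universe = set().union(*sets.values())
    for item in universe:
        membership[item] = tuple(ct for ct in cell_types if item in sets[ct])
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(cell_types) + 1):
        for subset in itertools.combinations(cell_types, r):
            counts[subset] = 0
    for combo in membership.values():
        counts[combo] += 1
    return IntersectionSummary(cell_types=cell_types, counts=counts)


def intersection_table(summary: IntersectionSummary) -> pd.DataFrame:
    rows = [
        {"subset": "&".join(subset), "degree": len(subset),
         "exclusive_count": count}
        for subset, count in summary.counts.items()
    ]
    return pd.DataFrame(rows).sort_values(
        ["degree", "subset"], kind="mergesort"
    ).reset_index(drop=True)


def unique_markers(
    sets: Mapping[str, set[str]],
    target: str,
    predicate: Callable[[str], bool] | None = None,
) -> list[str]:
    """Accessions present in ``target`` and in no other cell type."""
    if target not in sets:
        raise ValueError(f"unknown cell type {target!r}")
    others = set().union(
        *(s for ct, s in sets.items() if ct != target), set()
    )
    unique = sets[target] - others
    if predicate is not None:
        unique = {acc for acc in unique if predicate(acc)}
    return sorted(unique)


def min_max_scale_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to [0, 1]; zero-range rows map to all zeros."""
    values = matrix.to_numpy(dtype=float)
    lo = values.min(axis=1, keepdims=True)
    hi = values.max(axis=1, keepdims=True)
    span = hi - lo
    scaled = np.where(span > 0, (values - lo) / np.where(span == 0, 1, span), 0.0)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def cluster_markers(matrix: pd.DataFrame) -> ClusterResult:
    """Complete-linkage clustering of min-max-scaled protein profiles.

    Distances are Euclidean on row-scaled values; linkage is agglomerative
    complete (Lance-Williams max update) with deterministic tie-breaking:
    among minimum-distance pairs the lexicographically smallest (a, b)
    cluster-id pair merges first.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 proteins to cluster")
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 cell types to cluster")
    scaled = min_max_scale_rows(matrix)
    n = scaled.shape[0]
    dist = squareform(pdist(scaled.to_numpy(), metric="euclidean"))

    # active cluster id -> index into the working distance matrix
    active: dict[int, int] = {i: i for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    work = dist.copy()
    merges: list[tuple[int, int, float]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = work[active[a], active[b]]
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        d, a, b = best
        merges.append((a, b, float(d)))
        ia, ib = active[a], active[b]
        # complete linkage: d(new, k) = max(d(a, k), d(b, k))
        for c, ic in active.items():
            if c not in (a, b):
                m = max(work[ia, ic], work[ib, ic])
                work[ia, ic] = work[ic, ia] = m
        members[next_id] = members.pop(a) + members.pop(b)
        del active[b]
        active[next_id] = active.pop(a)
        next_id += 1

    order = members[next_id - 1]
    labels = tuple(str(x) for x in scaled.index)
    return ClusterResult(
        labels=labels,
        scaled=scaled,
        merges=tuple(merges),
        leaf_order=tuple(labels[i] for i in order),
    )


def cluster_table(result: ClusterResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"step": i, "cluster_a": a, "cluster_b": b, "height": round(h, 9)}
            for i, (a, b, h) in enumerate(result.merges)
        ]
    )
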