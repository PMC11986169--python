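"""Proteome-wide peptide uniqueness index.

A peptide is proteotypic when it maps to exactly one protein in the
reference proteome. Two matching semantics are supported:

* ``substring`` (default) — a protein is a parent if the peptide occurs
  anywhere in its sequence, regardless of tryptic context. This is the
  conservative uniqueness definition used by assay-design tools.
* ``digest`` — a protein is a parent only if its in-silico tryptic
  digest (per the supplied parameters) yields the peptide.

Optionally L and I are treated as identical (they are isobaric and
indistinguishable by mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digestion import DigestParams, digest_protein
from .proteome_io import ProteinRecord, write_tsv, read_tsv

PROTEOTYPIC = "proteotypic"
SHARED = "shared"
ABSENT = "absent"


def _canon(seq: str, equate_li: bool) -> str:
    return seq.replace("I", "L") if equate_li else seq


@dataclass
class ProteotypicityIndex:
    """Mapping peptide sequence -> sorted tuple of parent accessions."""

    parents: dict[str, tuple[str, ...]]
    sequences: dict[str, str]  # accession -> protein sequence, for live queries
    mode: str = "substring"
    equate_leucine_isoleucine: bool = False
    proteome_id: str = ""
    digest_params: DigestParams = field(default_factory=DigestParams)

    def parents_of(self, peptide: str) -> tuple[str, ...]:
        """Parent accessions of ``peptide``, computed on the fly if unindexed."""
        if peptide in self.parents:
            return self.parents[peptide]
        return self._scan(peptide)

    def _scan(self, peptide: str) -> tuple[str, ...]:
        eq = self.equate_leucine_isoleucine
        query = _canon(peptide, eq)
        hits = []
        for acc, seq in self.sequences.items():
            cseq = _canon(seq, eq)
            if self.mode == "digest":
                if self._is_digest_product(query, cseq):
                    hits.append(acc)
            elif query in cseq:
                hits.append(acc)
        return tuple(sorted(hits))

    def _is_digest_product(self, peptide: str, seq: str) -> bool:
        """Whether ``peptide`` occurs in ``seq`` with tryptic boundaries."""
        from .digestion import cleavage_sites

        p = self.digest_params
        if not p.min_length <= len(peptide) <= p.max_length:
            return False
        sites = set(cleavage_sites(seq, p.cleave_before_proline))
        i = seq.find(peptide)
        while i != -1:
            j = i + len(peptide)
            if (
                (i == 0 or (i - 1) in sites)
                and (j == len(seq) or (j - 1) in sites)
                and sum(1 for s in sites if i <= s < j - 1)
                <= p.max_missed_cleavages
            ):
                return True
            i = seq.find(peptide, i + 1)
        return False

    def is_proteotypic(self, peptide: str) -> bool:
        return len(self.parents_of(peptide)) == 1


def build_index(
    proteins: Sequence[ProteinRecord],
    mode: str = "substring",
    params: DigestParams | None = None,
    equate_leucine_isoleucine: bool = False,
    proteome_id: str = "",
) -> ProteotypicityIndex:
    """Digest every protein and index each peptide's parent set.

    In substring mode parents are found by scanning all protein sequences
    with a per-length sliding window (peptides grouped by length, window
    contents checked against a hash set — not a per-peptide ``find`` loop,
    so the test oracle stays an independent route).
    """
    if not proteins:
        raise ValueError("empty proteome: cannot build a proteotypicity index")
    if mode not in ("substring", "digest"):
        raise ValueError(f"unknown index mode {mode!r}")
    params = params or DigestParams()
    eq = equate_leucine_isoleucine

    sequences = {p.accession: p.sequence for p in proteins}
    # Candidate peptides: the tryptic digest of every protein.
    peptide_seqs: set[str] = set()
    digest_parents: dict[str, set[str]] = {}
    for prot in proteins:
        for pep in digest_protein(prot, params, carbamidomethyl_cys=False):
            peptide_seqs.add(pep.sequence)
            digest_parents.setdefault(_canon(pep.sequence, eq), set()).add(
                prot.accession
            )

    parents: dict[str, tuple[str, ...]]
    if mode == "digest":
        parents = {
            pep: tuple(sorted(digest_parents[_canon(pep, eq)]))
            for pep in peptide_seqs
        }
    else:
        by_len: dict[int, dict[str, set[str]]] = {}
        for pep in peptide_seqs:
            by_len.setdefault(len(pep), {}).setdefault(_canon(pep, eq), set())
        for acc, seq in sequences.items():
            cseq = _canon(seq, eq)
            for length, bucket in by_len.items():
                for i in range(len(cseq) - length + 1):
                    window = cseq[i : i + length]
                    if window in bucket:
                        bucket[window].add(acc)
        parents = {}
        for pep in peptide_seqs:
            parents[pep] = tuple(sorted(by_len[len(pep)][_canon(pep, eq)]))

    return ProteotypicityIndex(
        parents=parents,
        sequences=sequences,
        mode=mode,
        equate_leucine_isoleucine=eq,
        proteome_id=proteome_id,
        digest_params=params,
    )


def classify_peptide(
    index: ProteotypicityIndex, peptide: str
) -> tuple[str, tuple[str, ...]]:
    """Classify ``peptide`` as proteotypic / shared / absent with its parents."""
    parents = index.parents_of(peptide)
    if not parents:
        return ABSENT, parents
    if len(parents) == 1:
        return PROTEOTYPIC, parents
    return SHARED, parents


def index_table(index: ProteotypicityIndex) -> pd.DataFrame:
    """Flat view of the index: peptide, semicolon-joined parents, status."""
    rows = [
        {
            "peptide": pep,
            "parents": ";".join(parents),
            "n_parents": len(parents),
        }
        for pep, parents in sorted(index.parents.items())
    ]
    return pd.DataFrame(rows)


def export_index(index: ProteotypicityIndex, path: str | Path) -> None:
    write_tsv(
        index_table(index),
        path,
        comment=(
            f"proteotypicity index mode={index.mode} "
            f"equate_LI={index.equate_leucine_isoleucine} "
            f"proteome={index.proteome_id}"
        ),
    )


def import_index(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Load the peptide -> parents mapping of an exported index."""
    df = read_tsv(path)
    return {
        row.peptide: tuple(row.parents.split(";"))
        for row in df.itertuples(index=False)
    }
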