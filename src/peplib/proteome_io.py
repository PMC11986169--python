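"""Proteome FASTA input/output and protein mass computation.

Reads UniProt-style (``sp|ACC|NAME``) and plain-header FASTA files into
:class:`ProteinRecord` objects, computes average/monoisotopic protein
masses, and writes the tabular (TSV) outputs shared by the other modules.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .constants import (
    RESIDUE_AVG,
    RESIDUE_MONO,
    STANDARD_AMINO_ACIDS,
    WATER_AVG,
    WATER_MONO,
)

logger = logging.getLogger(__name__)

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|\s]+)\|(\S+)")
_GENE_SYMBOL = re.compile(r"\bGN=(\S+)")


class ProteomeError(ValueError):
    """Invalid proteome input (malformed FASTA, duplicates, bad residues)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry.

    Parameters
    ----------
    accession : str
        UniProt-style accession (e.g. ``"P10300"``) or the first
        whitespace-delimited header token for plain headers.
    description : str
        Free-text description from the FASTA header.
    sequence : str
        Uppercase amino-acid sequence over the 20 standard letters.
    gene_symbol : str
        Parsed from the ``GN=`` header field when present, else ``""``.
    """

    accession: str
    description: str
    sequence: str
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteomeError(f"empty sequence for {self.accession!r}")
        bad = set(self.sequence) - STANDARD_AMINO_ACIDS
        if bad:
            raise ProteomeError(
                f"sequence of {self.accession!r} contains disallowed "
                f"characters: {''.join(sorted(bad))}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def mass(self) -> float:
        """Average molecular mass in Daltons (protein-level reporting)."""
        return protein_mass(self.sequence, scale="average")


def protein_mass(sequence: str, scale: str = "average") -> float:
    """Mass of an unmodified polypeptide chain in Daltons.

    Sum of residue masses plus one water, on the requested scale
    (``"average"`` or ``"monoisotopic"``).
    """
    if not sequence:
        raise ProteomeError("cannot compute mass of an empty sequence")
    if scale == "average":
        table, water = RESIDUE_AVG, WATER_AVG
    elif scale == "monoisotopic":
        table, water = RESIDUE_MONO, WATER_MONO
    else:
        raise ValueError(f"unknown mass scale {scale!r}")
    try:
        return sum(table[aa] for aa in sequence) + water
    except KeyError as exc:
        raise ProteomeError(f"unknown residue {exc.args[0]!r}") from exc


def _parse_header(header: str) -> tuple[str, str, str]:
    """Split a FASTA header into (accession, description, gene_symbol)."""
    m = _UNIPROT_HEADER.match(header)
    if m:
        accession = m.group(1)
        rest = header[m.end() :].strip()
    else:
        parts = header.split(None, 1)
        accession = parts[0]
        rest = parts[1].strip() if len(parts) > 1 else ""
    gene = _GENE_SYMBOL.search(header)
    return accession, rest, gene.group(1) if gene else ""


def read_fasta(path: str | Path, lenient: bool = False) -> list[ProteinRecord]:
    """Read a proteome FASTA file into a list of :class:`ProteinRecord`.

    Accessions are parsed from ``sp|ACC|NAME`` / ``tr|ACC|NAME`` headers,
    falling back to the first whitespace-delimited token. Entry order is
    preserved.

    Parameters
    ----------
    lenient : bool
        When True, records with non-standard residues are skipped with a
        logged warning instead of raising.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    # fasta-pearson: permits ';' comment lines (used for seed provenance)
    for entry in SeqIO.parse(str(path), "fasta-pearson"):
        accession, description, gene = _parse_header(entry.description)
        if accession in seen:
            raise ProteomeError(f"duplicate accession {accession!r} in {path}")
        try:
            rec = ProteinRecord(
                accession=accession,
                description=description,
                sequence=str(entry.seq).upper(),
                gene_symbol=gene,
            )
        except ProteomeError as exc:
            if lenient:
                logger.warning("skipping %s: %s", accession, exc)
                continue
            raise
        seen.add(accession)
        records.append(rec)
    if not records:
        raise ProteomeError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                comment: str | None = None) -> None:
    """Write records as FASTA, re-synthesising UniProt-style headers.

    An optional ``;``-prefixed comment line is written before the first
    entry (legal FASTA, ignored by parsers) for provenance.
    """
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            fh.write(f"; {comment}\n")
        for rec in records:
            header = f">{rec.accession}"
            if rec.description:
                header += f" {rec.description}"
            if rec.gene_symbol and f"GN={rec.gene_symbol}" not in header:
                header += f" GN={rec.gene_symbol}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def protein_table(records: Sequence[ProteinRecord]) -> pd.DataFrame:
    """Protein-level summary table (accession, description, gene, length, mass)."""
    return pd.DataFrame(
        {
            "accession": [r.accession for r in records],
            "description": [r.description for r in records],
            "gene_symbol": [r.gene_symbol for r in records],
            "length": [r.length for r in records],
            "mass_avg": [round(r.mass, 5) for r in records],
        }
    )


def write_tsv(df: pd.DataFrame, path: str | Path, comment: str | None = None,
              float_format: str | None = None) -> None:
    """Write a DataFrame as UTF-8 TSV with a header row and '.' decimals."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format,
                  lineterminator="\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` (``#`` comments skipped)."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
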