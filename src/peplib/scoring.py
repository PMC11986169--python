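"""Additive peptide-ranking score for targeted-assay (PRM/MRM) design.

Ten boolean criteria are evaluated per peptide; uniqueness within the
proteome contributes 2 points, every other criterion 1, giving a total
in 0..11:

==== ==================================================== =========
flag criterion                                            increment
==== ==================================================== =========
c1   present in the spectral library                      +1
c2   proteotypic (unique within the proteome)             +2
c3   length of 6-25 amino acids                           +1
c4   no missed tryptic cleavages                          +1
c5   contains neither Met nor Cys                         +1
c6   N-terminal residue is neither Trp nor Glu            +1
c7   no Pro-Pro                                           +1
c8   no Asp-Pro                                           +1
c9   no Asp-Gly                                           +1
c10  no run of more than three consecutive Ser            +1
==== ==================================================== =========

c1 and c2 are supplied by the caller (library table / proteotypicity
index) so hypothetical, not-yet-measured peptides can be ranked too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .digestion import DigestPeptide

CRITERIA = ("c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8", "c9", "c10")
INCREMENTS = {c: (2 if c == "c2" else 1) for c in CRITERIA}
MAX_SCORE = sum(INCREMENTS.values())  # 11


@dataclass(frozen=True)
class PeptideScoreBreakdown:
    peptide: str
    c1: bool
    c2: bool
    c3: bool
    c4: bool
    c5: bool
    c6: bool
    c7: bool
    c8: bool
    c9: bool
    c10: bool

    @property
    def flags(self) -> dict[str, bool]:
        return {c: getattr(self, c) for c in CRITERIA}

    @property
    def total(self) -> int:
        return sum(INCREMENTS[c] for c, on in self.flags.items() if on)


def score_peptide(
    peptide: DigestPeptide | str,
    *,
    in_library: bool,
    proteotypic: bool,
    missed_cleavages: int | None = None,
) -> PeptideScoreBreakdown:
    """Evaluate all ten criteria on a peptide.

    ``peptide`` may be a :class:`DigestPeptide` (its missed-cleavage count
    is used) or a bare sequence, in which case ``missed_cleavages`` is
    required. Pure function: no hidden state.
    """
    if isinstance(peptide, DigestPeptide):
        seq = peptide.sequence
        mc = peptide.missed_cleavages
    else:
        seq = peptide
        if missed_cleavages is None:
            raise ValueError("missed_cleavages required for a bare sequence")
        mc = missed_cleavages
    if not seq:
        raise ValueError("empty peptide sequence")
    return PeptideScoreBreakdown(
        peptide=seq,
        c1=bool(in_library),
        c2=bool(proteotypic),
        c3=6 <= len(seq) <= 25,
        c4=mc == 0,
        c5="M" not in seq and "C" not in seq,
        c6=seq[0] not in "WE",
        c7="PP" not in seq,
        c8="DP" not in seq,
        c9="DG" not in seq,
        c10="SSSS" not in seq,
    )


def rank_peptides(
    breakdowns: Sequence[PeptideScoreBreakdown],
) -> list[PeptideScoreBreakdown]:
    """Descending by total; ties broken by shorter length, then sequence."""
    return sorted(
        breakdowns, key=lambda b: (-b.total, len(b.peptide), b.peptide)
    )


def score_table(
    breakdowns: Sequence[PeptideScoreBreakdown],
    accessions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Score TSV table: accession, sequence, c1..c10 as 0/1, total."""
    rows = []
    for i, b in enumerate(breakdowns):
        row = {"accession": accessions[i] if accessions is not None else ""}
        row["sequence"] = b.peptide
        for c in CRITERIA:
            row[c] = int(getattr(b, c))
        row["total"] = b.total
        rows.append(row)
    return pd.DataFrame(rows)
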