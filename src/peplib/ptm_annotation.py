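"""PTM record validation, FDR/proteotypicity filtering and site projection.

Integration rules: a modified-peptide observation is kept only if the
peptide is proteotypic for the stated accession and passes its q-value
gate (< 0.01 by default). N-glycosylation records additionally pass a
glycan-level q-value gate and the glyco search-space gates (peptide mass
600-4000 Da, length 6-40, at most 2 modification sites per peptide).
Kept records are projected from peptide to protein coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .proteome_io import ProteinRecord
from .proteotypicity import ProteotypicityIndex

PROTEIN_N_TERM = "protein-N-term"

MOD_TYPES = (
    "oxidation",
    "phosphorylation",
    "monomethylation",
    "deamidation",
    "acetylation",
    "n_glycosylation",
)

# Acetylation allows K, R and the protein N-terminus (union of the two
# conventions in circulation); the vocabulary is caller-configurable.
DEFAULT_RESIDUE_VOCAB: dict[str, frozenset[str]] = {
    "oxidation": frozenset("M"),
    "phosphorylation": frozenset("STY"),
    "monomethylation": frozenset("KR"),
    "deamidation": frozenset("NQ"),
    "acetylation": frozenset("KR") | {PROTEIN_N_TERM},
    "n_glycosylation": frozenset("N"),
}

# Rejection reason codes, in the order gates are applied.
REASON_UNKNOWN_ACCESSION = "unknown_accession"
REASON_NOT_PROTEOTYPIC = "not_proteotypic"
REASON_PARENT_MISMATCH = "parent_mismatch"
REASON_INVALID_RESIDUE = "invalid_residue"
REASON_Q_VALUE = "q_value"
REASON_GLYCO_Q_VALUE = "glyco_q_value"
REASON_GLYCO_MASS = "glyco_mass"
REASON_GLYCO_LENGTH = "glyco_length"
REASON_GLYCO_MOD_COUNT = "glyco_mod_count"


@dataclass(frozen=True)
class PtmRecord:
    """One modified-peptide observation from an upstream search."""

    cell_type: str
    peptide: str
    accession: str
    mod_type: str
    site_residue: str  # amino-acid letter or "protein-N-term"
    site_position_in_peptide: int  # 1-based
    q_value: float
    glycan_composition: str | None = None
    glycan_q_value: float | None = None
    peptide_mass: float | None = None

    def __post_init__(self) -> None:
        if self.mod_type not in MOD_TYPES:
            raise ValueError(f"unknown mod_type {self.mod_type!r}")
        if not 1 <= self.site_position_in_peptide <= len(self.peptide):
            raise ValueError(
                f"site position {self.site_position_in_peptide} outside "
                f"peptide of length {len(self.peptide)}"
            )
        if not 0 <= self.q_value <= 1:
            raise ValueError(f"q_value {self.q_value} outside [0, 1]")
        is_glyco = self.mod_type == "n_glycosylation"
        has_glyco_fields = (
            self.glycan_composition is not None or self.glycan_q_value is not None
        )
        if is_glyco and (self.glycan_composition is None
                         or self.glycan_q_value is None):
            raise ValueError("n_glycosylation records need glycan fields")
        if not is_glyco and has_glyco_fields:
            raise ValueError("glycan fields only allowed for n_glycosylation")


@dataclass(frozen=True)
class PtmFilterParams:
    q_max: float = 0.01
    glyco_q_max: float = 0.01
    glyco_mass_range: tuple[float, float] = (600.0, 4000.0)
    glyco_length_range: tuple[int, int] = (6, 40)
    glyco_max_mods_per_peptide: int = 2
    residue_vocab: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_RESIDUE_VOCAB)
    )

    def __post_init__(self) -> None:
        if not 0 < self.q_max <= 1 or not 0 < self.glyco_q_max <= 1:
            raise ValueError("q thresholds must be in (0, 1]")
        if not 0 < self.glyco_mass_range[0] <= self.glyco_mass_range[1]:
            raise ValueError("glyco_mass_range must be positive and ordered")
        if not 0 < self.glyco_length_range[0] <= self.glyco_length_range[1]:
            raise ValueError("glyco_length_range must be positive and ordered")
        if self.glyco_max_mods_per_peptide < 1:
            raise ValueError("glyco_max_mods_per_peptide must be >= 1")


@dataclass(frozen=True)
class FilterResult:
    kept: tuple[PtmRecord, ...]
    rejected: tuple[tuple[PtmRecord, str], ...]


@dataclass(frozen=True)
class SiteAnnotation:
    """A modification projected onto protein coordinates (1-based)."""

    accession: str
    position: int
    residue: str
    mod_type: str
    cell_types: tuple[str, ...]
    ambiguous_position: bool = False


def _mod_sites_per_peptide(
    records: Sequence[PtmRecord],
) -> dict[tuple[str, str, str], int]:
    """Distinct modification sites observed on each (cell, peptide, acc)."""
    sites: dict[tuple[str, str, str], set[tuple[str, int]]] = {}
    for r in records:
        key = (r.cell_type, r.peptide, r.accession)
        sites.setdefault(key, set()).add(
            (r.mod_type, r.site_position_in_peptide)
        )
    return {k: len(v) for k, v in sites.items()}


def _reject_reason(
    r: PtmRecord,
    index: ProteotypicityIndex,
    params: PtmFilterParams,
    n_mods: Mapping[tuple[str, str, str], int],
) -> str | None:
    if r.accession not in index.sequences:
        return REASON_UNKNOWN_ACCESSION
    parents = index.parents_of(r.peptide)
    if len(parents) != 1:
        return REASON_NOT_PROTEOTYPIC
    if parents[0] != r.accession:
        return REASON_PARENT_MISMATCH
    allowed = params.residue_vocab.get(r.mod_type, frozenset())
    if r.site_residue == PROTEIN_N_TERM:
        if PROTEIN_N_TERM not in allowed:
            return REASON_INVALID_RESIDUE
    else:
        if (r.site_residue not in allowed
                or r.peptide[r.site_position_in_peptide - 1] != r.site_residue):
            return REASON_INVALID_RESIDUE
    if not r.q_value < params.q_max:
        return REASON_Q_VALUE
    if r.mod_type == "n_glycosylation":
        if not r.glycan_q_value < params.glyco_q_max:
            return REASON_GLYCO_Q_VALUE
        lo, hi = params.glyco_mass_range
        if r.peptide_mass is None or not lo <= r.peptide_mass <= hi:
            return REASON_GLYCO_MASS
        llo, lhi = params.glyco_length_range
        if not llo <= len(r.peptide) <= lhi:
            return REASON_GLYCO_LENGTH
        key = (r.cell_type, r.peptide, r.accession)
        if n_mods.get(key, 1) > params.glyco_max_mods_per_peptide:
            return REASON_GLYCO_MOD_COUNT
    return None


def filter_ptms(
    records: Sequence[PtmRecord],
    index: ProteotypicityIndex,
    params: PtmFilterParams = PtmFilterParams(),
) -> FilterResult:
    """Partition records into kept and rejected-with-reason.

    Gates are applied in a fixed order (accession, proteotypicity, parent
    identity, residue vocabulary, peptide q-value, then the glyco gates);
    the reported reason is the first failing gate. The kept and rejected
    sets partition the input exactly.
    """
    n_mods = _mod_sites_per_peptide(records)
    kept: list[PtmRecord] = []
    rejected: list[tuple[PtmRecord, str]] = []
    for r in records:
        reason = _reject_reason(r, index, params, n_mods)
        if reason is None:
            kept.append(r)
        else:
            rejected.append((r, reason))
    return FilterResult(kept=tuple(kept), rejected=tuple(rejected))


def project_sites(
    protein: ProteinRecord, kept: Sequence[PtmRecord]
) -> list[SiteAnnotation]:
    """Project kept records for one protein onto protein coordinates.

    Protein position = peptide start + in-peptide position - 1 (1-based).
    If the peptide occurs more than once in the protein, every occurrence
    is annotated and flagged ambiguous. Duplicate (position, mod_type)
    pairs are collapsed with their observing cell types merged.
    """
    merged: dict[tuple[int, str], set[str]] = {}
    ambiguous: dict[tuple[int, str], bool] = {}
    for r in kept:
        if r.accession != protein.accession:
            raise ValueError(
                f"record accession {r.accession!r} does not match protein "
                f"{protein.accession!r}"
            )
        starts = _occurrences(protein.sequence, r.peptide)
        if not starts:
            raise ValueError(
                f"peptide {r.peptide!r} not found in {protein.accession}"
            )
        for start0 in starts:
            pos = start0 + r.site_position_in_peptide  # start0 is 0-based
            residue = protein.sequence[pos - 1]
            if r.site_residue != PROTEIN_N_TERM and residue != r.site_residue:
                raise ValueError(
                    f"residue mismatch at {protein.accession} position {pos}: "
                    f"expected {r.site_residue}, found {residue}"
                )
            key = (pos, r.mod_type)
            merged.setdefault(key, set()).add(r.cell_type)
            ambiguous[key] = ambiguous.get(key, False) or len(starts) > 1
    return [
        SiteAnnotation(
            accession=protein.accession,
            position=pos,
            residue=protein.sequence[pos - 1],
            mod_type=mod,
            cell_types=tuple(sorted(cells)),
            ambiguous_position=ambiguous[(pos, mod)],
        )
        for (pos, mod), cells in sorted(merged.items())
    ]


def _occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrence starts."""
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


# --- TSV dialect -----------------------------------------------------------

PTM_COLUMNS = (
    "cell_type", "peptide", "accession", "mod_type", "site",
    "q_value", "glycan_composition", "glycan_q_value", "peptide_mass",
)


def _format_site(r: PtmRecord) -> str:
    if r.site_residue == PROTEIN_N_TERM:
        return "N-term"
    return f"{r.site_residue}{r.site_position_in_peptide}"


def _parse_site(site: str) -> tuple[str, int]:
    if site == "N-term":
        return PROTEIN_N_TERM, 1
    return site[0], int(site[1:])


def ptm_records_to_table(records: Sequence[PtmRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "cell_type": r.cell_type,
            "peptide": r.peptide,
            "accession": r.accession,
            "mod_type": r.mod_type,
            "site": _format_site(r),
            "q_value": r.q_value,
            "glycan_composition": r.glycan_composition or "",
            "glycan_q_value": "" if r.glycan_q_value is None else r.glycan_q_value,
            "peptide_mass": "" if r.peptide_mass is None else r.peptide_mass,
        })
    return pd.DataFrame(rows, columns=list(PTM_COLUMNS))


def ptm_records_from_table(df: pd.DataFrame) -> list[PtmRecord]:
    records = []
    for row in df.itertuples(index=False):
        residue, pos = _parse_site(str(row.site))
        glycan = getattr(row, "glycan_composition", None)
        glycan = None if pd.isna(glycan) or glycan == "" else str(glycan)
        gq = getattr(row, "glycan_q_value", None)
        gq = None if pd.isna(gq) or gq == "" else float(gq)
        pm = getattr(row, "peptide_mass", None)
        pm = None if pd.isna(pm) or pm == "" else float(pm)
        records.append(PtmRecord(
            cell_type=str(row.cell_type),
            peptide=str(row.peptide),
            accession=str(row.accession),
            mod_type=str(row.mod_type),
            site_residue=residue,
            site_position_in_peptide=pos,
            q_value=float(row.q_value),
            glycan_composition=glycan,
            glycan_q_value=gq,
            peptide_mass=pm,
        ))
    return records


def sites_table(annotations: Sequence[SiteAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "accession": a.accession,
            "position": a.position,
            "residue": a.residue,
            "mod_type": a.mod_type,
            "cell_types": ";".join(a.cell_types),
            "ambiguous_position": int(a.ambiguous_position),
        }
        for a in annotations
    ])
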