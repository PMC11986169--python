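"""Deterministic synthetic proteomes and evidence tables with planted truth.

Every module in the toolkit is testable offline against fixtures built
here: random proteomes with peptides planted in known hosts (so true
parent sets are known), spectral counts engineered so NSAF recovers
planted proportions, and PTM records with known filter outcomes.

All randomness flows from a single integer seed; the same seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import DigestParams, digest_protein, peptide_mono_mass
from .proteome_io import ProteinRecord, write_fasta, write_tsv
from .proteotypicity import build_index
from .ptm_annotation import (
    PROTEIN_N_TERM,
    PtmRecord,
    ptm_records_to_table,
)

_ALPHABET = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class PlantedPtm:
    """A PTM record template plus its expected filter outcome."""

    record: PtmRecord
    expected: str  # "kept" or a rejection reason code


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_proteins: int = 12
    length_range: tuple[int, int] = (90, 150)
    cell_types: tuple[str, ...] = ("typeA", "typeB", "typeC")
    # (peptide sequence, host accessions); hosts >= 2 means planted-shared
    planted_peptides: tuple[tuple[str, tuple[str, ...]], ...] = ()
    # cell_type -> accession -> target nsaf proportion (sums to 1)
    planted_abundances: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict
    )
    planted_ptms: tuple[PlantedPtm, ...] = ()
    count_scale: int = 3000
    peptides_per_protein: int = 5

    def __post_init__(self) -> None:
        for ct, props in self.planted_abundances.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"planted abundances for {ct!r} sum to {total}, not 1"
                )


def accession_for(i: int) -> str:
    return f"P{i + 1:05d}"


@dataclass(frozen=True)
class Fixture:
    """Generated evidence bundle with its ground truth."""

    counts: pd.DataFrame  # cell_type, accession, spectral_count
    evidence: pd.DataFrame  # cell_type, peptide, accession
    ptm_records: tuple[PtmRecord, ...]
    truth_uniqueness: pd.DataFrame  # peptide, expected_parents
    truth_abundance: pd.DataFrame  # cell_type, accession, planted_nsaf
    truth_ptm: pd.DataFrame  # row-aligned with ptm_records: expected outcome


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_ALPHABET, size=length))


def _plant(sequence: str, peptide: str, pos: int) -> str:
    """Splice a tryptic peptide into ``sequence`` at 0-based ``pos``.

    The residue before the peptide is forced to K (a cleavage site) and a
    following proline is rewritten to A so the peptide's own C-terminal
    K/R cleaves.
    """
    end = pos + len(peptide)
    out = sequence[: pos - 1] + "K" + peptide + sequence[end:]
    if end < len(out) and out[end] == "P":
        out = out[:end] + "A" + out[end + 1 :]
    return out


def generate_proteome(
    spec: FixtureSpec,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Random proteome with planted peptides and their true parent sets.

    Planted peptides must end in K or R (so they are tryptic) and fit
    inside their hosts with one residue of flank on each side. The
    returned ground-truth table is verified against a full substring scan
    of the generated sequences; an accidental extra occurrence of a
    planted peptide triggers a redraw of the offending host.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    planted_by_host: dict[str, list[str]] = {}
    for pep, hosts in spec.planted_peptides:
        if not pep or pep[-1] not in "KR":
            raise ValueError(f"planted peptide {pep!r} must end in K or R")
        for host in hosts:
            planted_by_host.setdefault(host, []).append(pep)

    records: list[ProteinRecord] = []
    for i in range(spec.n_proteins):
        acc = accession_for(i)
        length = int(rng.integers(lo, hi + 1))
        needed = sum(len(p) + 2 for p in planted_by_host.get(acc, []))
        if needed > length:
            raise ValueError(
                f"planted peptides ({needed} residues with flanks) do not fit "
                f"in host {acc} of length {length}"
            )
        seq = _random_sequence(rng, length)
        cursor = 1
        for pep in planted_by_host.get(acc, []):
            seq = _plant(seq, pep, cursor)
            cursor += len(pep) + 2
        records.append(
            ProteinRecord(
                accession=acc,
                description=f"synthetic protein {acc}",
                sequence=seq,
                gene_symbol=f"Syn{i + 1}",
            )
        )

    # Verify planted parent sets against a direct substring scan; redraw
    # hosts whose random flanks created accidental occurrences.
    for _attempt in range(20):
        offenders = _accidental_hosts(records, spec)
        if not offenders:
            break
        for idx in offenders:
            rec = records[idx]
            length = len(rec.sequence)
            seq = _random_sequence(rng, length)
            cursor = 1
            for pep in planted_by_host.get(rec.accession, []):
                seq = _plant(seq, pep, cursor)
                cursor += len(pep) + 2
            records[idx] = replace(rec, sequence=seq)
    else:
        raise RuntimeError("could not plant peptides without collisions")

    truth = pd.DataFrame(
        [
            {"peptide": pep, "expected_parents": ";".join(sorted(hosts))}
            for pep, hosts in spec.planted_peptides
        ]
    )
    return records, truth


def _accidental_hosts(
    records: Sequence[ProteinRecord], spec: FixtureSpec
) -> list[int]:
    """Indices of records containing a planted peptide they should not."""
    offenders = []
    for i, rec in enumerate(records):
        for pep, hosts in spec.planted_peptides:
            if rec.accession not in hosts and pep in rec.sequence:
                offenders.append(i)
                break
    return offenders


def generate_evidence(
    spec: FixtureSpec, proteome: Sequence[ProteinRecord]
) -> Fixture:
    """Spectral counts, peptide evidence and PTM records with ground truth.

    Counts are round(K * planted_nsaf * length) so that NSAF recomputation
    recovers the planted proportions to within rounding error. Peptide
    evidence lists the first few proteotypic digest peptides of each
    protein with positive abundance, plus every planted peptide for its
    hosts.
    """
    by_acc = {p.accession: p for p in proteome}
    index = build_index(list(proteome), mode="substring")

    count_rows = []
    for ct in spec.cell_types:
        props = spec.planted_abundances.get(ct, {})
        for acc in sorted(props):
            prop = props[acc]
            protein = by_acc[acc]
            count = round(spec.count_scale * prop * protein.length)
            if prop > 0 and count == 0:
                raise ValueError(
                    f"count_scale={spec.count_scale} too small to represent "
                    f"proportion {prop} for {acc}; increase count_scale"
                )
            count_rows.append(
                {"cell_type": ct, "accession": acc, "spectral_count": count}
            )
    counts = pd.DataFrame(count_rows)

    evidence_rows = []
    for ct in spec.cell_types:
        props = spec.planted_abundances.get(ct, {})
        for acc in sorted(props):
            if props[acc] <= 0:
                continue
            taken = 0
            for pep in digest_protein(by_acc[acc], DigestParams(),
                                      carbamidomethyl_cys=False):
                if taken >= spec.peptides_per_protein:
                    break
                parents = index.parents_of(pep.sequence)
                if len(parents) == 1 and parents[0] == acc:
                    evidence_rows.append(
                        {"cell_type": ct, "peptide": pep.sequence,
                         "accession": acc}
                    )
                    taken += 1
            for pep, hosts in spec.planted_peptides:
                if acc in hosts:
                    evidence_rows.append(
                        {"cell_type": ct, "peptide": pep, "accession": acc}
                    )
    evidence = pd.DataFrame(evidence_rows).drop_duplicates().reset_index(
        drop=True
    )

    records = tuple(p.record for p in spec.planted_ptms)
    truth_ptm = pd.DataFrame(
        [
            {
                "row": i,
                "peptide": p.record.peptide,
                "mod_type": p.record.mod_type,
                "expected": p.expected,
            }
            for i, p in enumerate(spec.planted_ptms)
        ]
    )
    truth_abundance = pd.DataFrame(
        [
            {"cell_type": ct, "accession": acc, "planted_nsaf": prop}
            for ct in spec.cell_types
            for acc, prop in sorted(spec.planted_abundances.get(ct, {}).items())
        ]
    )
    truth_uniqueness = pd.DataFrame(
        [
            {"peptide": pep, "expected_parents": ";".join(sorted(hosts))}
            for pep, hosts in spec.planted_peptides
        ]
    )
    return Fixture(
        counts=counts,
        evidence=evidence,
        ptm_records=records,
        truth_uniqueness=truth_uniqueness,
        truth_abundance=truth_abundance,
        truth_ptm=truth_ptm,
    )


def default_spec(seed: int = 1) -> FixtureSpec:
    """A standard fixture exercising every planted ground-truth category."""
    a1, a2, a3, a4, a5, a6 = (accession_for(i) for i in range(6))
    shared = "LNGTESTVIR"  # planted in two hosts -> never proteotypic
    ox_host = "ALMNTPEVK"  # Met for oxidation
    ph_host = "AGTSLDNVK"  # Ser/Thr for phosphorylation
    gl_host = "LVNGSDTIAK"  # Asn sequon for N-glycosylation
    gl_long = "G" * 20 + "N" + "G" * 20 + "K"  # 42 aa, mass in range
    gl_heavy = "W" * 24 + "NK"  # 26 aa but mass > 4000 Da
    gl_multi = "ANGTNLSNVTK"  # three Asn sites -> too many mods

    def glyco(cell, pep, host, pos, q=0.002, gq=0.003, mass=None):
        return PtmRecord(
            cell_type=cell, peptide=pep, accession=host,
            mod_type="n_glycosylation", site_residue="N",
            site_position_in_peptide=pos, q_value=q,
            glycan_composition="HexNAc(2)Hex(5)", glycan_q_value=gq,
            peptide_mass=mass if mass is not None else round(
                peptide_mono_mass(pep), 5),
        )

    planted_ptms = (
        PlantedPtm(PtmRecord("typeA", ox_host, a3, "oxidation", "M", 3, 0.005),
                   "kept"),
        PlantedPtm(PtmRecord("typeA", ph_host, a4, "phosphorylation", "S", 4,
                             0.001), "kept"),
        PlantedPtm(PtmRecord("typeB", ph_host, a4, "monomethylation", "K", 9,
                             0.004), "kept"),
        PlantedPtm(glyco("typeA", gl_host, a5, 3), "kept"),
        # failures, one per gate
        PlantedPtm(PtmRecord("typeA", shared, a1, "phosphorylation", "S", 6,
                             0.001), "not_proteotypic"),
        PlantedPtm(PtmRecord("typeA", ox_host, a3, "oxidation", "M", 3, 0.05),
                   "q_value"),
        PlantedPtm(PtmRecord("typeA", ox_host, "Z99999", "oxidation", "M", 3,
                             0.005), "unknown_accession"),
        PlantedPtm(PtmRecord("typeA", ph_host, a3, "phosphorylation", "S", 4,
                             0.001), "parent_mismatch"),
        PlantedPtm(PtmRecord("typeB", ph_host, a4, "phosphorylation", "S", 5,
                             0.001), "invalid_residue"),
        PlantedPtm(glyco("typeB", gl_host, a5, 3, gq=0.05), "glyco_q_value"),
        PlantedPtm(glyco("typeB", gl_heavy, a6, 25), "glyco_mass"),
        PlantedPtm(glyco("typeB", gl_long, a6, 21), "glyco_length"),
        PlantedPtm(glyco("typeC", gl_multi, a6, 2), "glyco_mod_count"),
        PlantedPtm(glyco("typeC", gl_multi, a6, 5), "glyco_mod_count"),
        PlantedPtm(glyco("typeC", gl_multi, a6, 8), "glyco_mod_count"),
    )
    return FixtureSpec(
        seed=seed,
        n_proteins=12,
        planted_peptides=(
            (shared, (a1, a2)),
            ("LGQSTR", (a3,)),
            (ox_host, (a3,)),
            (ph_host, (a4,)),
            (gl_host, (a5,)),
            (gl_long, (a6,)),
            (gl_heavy, (a6,)),
            (gl_multi, (a6,)),
        ),
        planted_abundances={
            "typeA": {a1: 0.4, a2: 0.3, a3: 0.2, a4: 0.1},
            "typeB": {a1: 0.25, a2: 0.25, a4: 0.25, a5: 0.25},
            "typeC": {a1: 0.5, a5: 0.3, a6: 0.2},
        },
        planted_ptms=planted_ptms,
    )


def write_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Materialise a fixture as plain-text files under ``out_dir``.

    Every file carries the seed in a comment header for provenance.
    Returns a name -> path mapping.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    proteome, truth_uniq = generate_proteome(spec)
    fixture = generate_evidence(spec, proteome)
    seed_note = f"seed={spec.seed}"

    paths = {
        "proteome": out_dir / "proteome.fasta",
        "counts": out_dir / "spectral_counts.tsv",
        "evidence": out_dir / "peptide_evidence.tsv",
        "ptms": out_dir / "ptm_records.tsv",
        "truth_uniqueness": out_dir / "truth_uniqueness.tsv",
        "truth_abundance": out_dir / "truth_abundance.tsv",
        "truth_ptm": out_dir / "truth_ptm.tsv",
    }
    write_fasta(proteome, paths["proteome"], comment=seed_note)
    write_tsv(fixture.counts, paths["counts"], comment=seed_note)
    write_tsv(fixture.evidence, paths["evidence"], comment=seed_note)
    write_tsv(ptm_records_to_table(list(fixture.ptm_records)), paths["ptms"],
              comment=seed_note)
    write_tsv(fixture.truth_uniqueness, paths["truth_uniqueness"],
              comment=seed_note)
    write_tsv(fixture.truth_abundance, paths["truth_abundance"],
              comment=seed_note, float_format="%.9g")
    write_tsv(fixture.truth_ptm, paths["truth_ptm"], comment=seed_note)
    return paths
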