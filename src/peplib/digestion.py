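"""In-silico tryptic digestion and peptide mass / precursor m/z computation.

Trypsin cleaves C-terminal to K and R; cleavage before proline is
suppressed by default ("Trypsin (full)" convention) and can be enabled
via :class:`DigestParams`. Peptides carry 1-based inclusive coordinates
on their parent and an exact internal missed-cleavage count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import (
    CARBAMIDOMETHYL_MASS,
    OXIDATION_MASS,
    PROTON_MASS,
    RESIDUE_MONO,
    WATER_MONO,
)
from .proteome_io import ProteinRecord

DEFAULT_CHARGES = (2, 3, 4)


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion settings.

    Defaults mirror a conventional database-search configuration:
    up to 2 missed cleavages and peptide lengths of 6-150 residues.
    """

    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 150
    cleave_before_proline: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")
        if not (1 <= self.min_length <= self.max_length):
            raise ValueError("need 1 <= min_length <= max_length")


@dataclass(frozen=True)
class DigestPeptide:
    """A tryptic peptide located on its parent protein.

    ``start``/``end`` are 1-based inclusive residue coordinates;
    ``mono_mass`` includes fixed modifications if applied at digestion.
    """

    sequence: str
    parent_accession: str
    start: int
    end: int
    missed_cleavages: int
    mono_mass: float

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")


def cleavage_sites(sequence: str, cleave_before_proline: bool = False) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    The protein C-terminus is never a site. With proline suppression
    (default) a K/R followed by P is not cut.
    """
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR":
            if not cleave_before_proline and sequence[i + 1] == "P":
                continue
            sites.append(i)
    return sites


def digest_protein(
    protein: ProteinRecord,
    params: DigestParams = DigestParams(),
    carbamidomethyl_cys: bool = True,
) -> list[DigestPeptide]:
    """All tryptic peptides of ``protein`` with 0..max missed cleavages.

    Returns peptides filtered to ``[min_length, max_length]``, ordered by
    (start, end). ``mono_mass`` carries fixed carbamidomethylation of Cys
    unless disabled.
    """
    seq = protein.sequence
    sites = cleavage_sites(seq, params.cleave_before_proline)
    # Fragment boundaries: starts and one-past-ends of fully cleaved pieces.
    bounds = [0] + [i + 1 for i in sites] + [len(seq)]
    peptides: list[DigestPeptide] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for mc in range(min(params.max_missed_cleavages, n_frag - 1 - i) + 1):
            lo, hi = bounds[i], bounds[i + mc + 1]
            if not (params.min_length <= hi - lo <= params.max_length):
                continue
            pep = seq[lo:hi]
            peptides.append(
                DigestPeptide(
                    sequence=pep,
                    parent_accession=protein.accession,
                    start=lo + 1,
                    end=hi,
                    missed_cleavages=mc,
                    mono_mass=peptide_mono_mass(
                        pep, carbamidomethyl_cys=carbamidomethyl_cys
                    ),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def count_missed_cleavages(sequence: str, cleave_before_proline: bool = False) -> int:
    """Internal (non-C-terminal) tryptic sites left uncut within a peptide."""
    return len(cleavage_sites(sequence, cleave_before_proline))


def peptide_mono_mass(
    sequence: str,
    carbamidomethyl_cys: bool = False,
    n_oxidations: int = 0,
) -> float:
    """Monoisotopic neutral peptide mass with optional modifications."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    try:
        mass = sum(RESIDUE_MONO[aa] for aa in sequence) + WATER_MONO
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    if carbamidomethyl_cys:
        mass += CARBAMIDOMETHYL_MASS * sequence.count("C")
    if n_oxidations:
        if n_oxidations > sequence.count("M"):
            raise ValueError(
                f"{n_oxidations} oxidations requested but sequence has only "
                f"{sequence.count('M')} Met"
            )
        mass += OXIDATION_MASS * n_oxidations
    return mass


def peptide_mz(
    sequence: str,
    charge: int,
    fixed_mods: Iterable[str] = ("carbamidomethyl",),
    variable_mods: Sequence[str] = (),
) -> float:
    """Precursor m/z in Thomson for a peptide at the given charge state.

    ``fixed_mods`` may contain ``"carbamidomethyl"`` (applied to every Cys);
    ``variable_mods`` is a multiset of ``"oxidation"`` entries, one per
    oxidised Met. A variable modification without a matching residue is an
    error, as is a charge outside 1..6.
    """
    if not 1 <= charge <= 6:
        raise ValueError(f"charge must be in 1..6, got {charge}")
    fixed = set(fixed_mods)
    unknown = fixed - {"carbamidomethyl"}
    if unknown:
        raise ValueError(f"unsupported fixed modifications: {sorted(unknown)}")
    n_ox = 0
    for mod in variable_mods:
        if mod != "oxidation":
            raise ValueError(f"unsupported variable modification {mod!r}")
        n_ox += 1
    mass = peptide_mono_mass(
        sequence,
        carbamidomethyl_cys="carbamidomethyl" in fixed,
        n_oxidations=n_ox,
    )
    return (mass + charge * PROTON_MASS) / charge


def peptide_table(
    peptides: Sequence[DigestPeptide],
    charges: Sequence[int] = DEFAULT_CHARGES,
) -> pd.DataFrame:
    """Peptide-level TSV table with m/z columns for the given charge states."""
    rows = []
    for p in peptides:
        row = {
            "accession": p.parent_accession,
            "sequence": p.sequence,
            "start": p.start,
            "end": p.end,
            "missed_cleavages": p.missed_cleavages,
            "mono_mass": round(p.mono_mass, 5),
        }
        for z in charges:
            row[f"mz_z{z}"] = round((p.mono_mass + z * PROTON_MASS) / z, 5)
        rows.append(row)
    return pd.DataFrame(rows)
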