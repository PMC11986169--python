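# peplib

Toolkit for designing targeted mass-spectrometry (PRM/MRM) assays from
cell-type proteomics evidence:

- **proteome_io** — FASTA proteome reading (UniProt-style and plain headers),
  protein average/monoisotopic mass, TSV writers.
- **digestion** — in-silico tryptic digestion (missed cleavages, optional
  cleavage before proline), peptide monoisotopic mass and precursor m/z with
  fixed carbamidomethyl-Cys and variable Met oxidation.
- **proteotypicity** — proteome-wide peptide → parent-protein index
  (substring or digest semantics, optional Leu/Ile equivalence);
  a peptide is proteotypic when it has exactly one parent.
- **scoring** — additive ten-criterion peptide-ranking score (0–11):
  library presence +1, proteome uniqueness +2, length 6–25 +1, no missed
  cleavages +1, no Met/Cys +1, N-terminus not Trp/Glu +1, no PP/DP/DG motifs
  +1 each, no run of more than three Ser +1.
- **quantification** — NSAF relative abundance from spectral counts
  (saf = count/length, normalised per cell type), dynamic range, rank tables.
- **ptm_annotation** — PTM record validation and filtering (proteotypic-only,
  q < 0.01; glycopeptides additionally glycan q < 0.01, mass 600–4000 Da,
  length 6–40, ≤ 2 modification sites), projection onto protein coordinates.
- **library_assembly** — per-cell-type library tables, exclusive (upset-style)
  intersection counts, unique markers, complete-linkage clustering of
  min-max-scaled abundance profiles.
- **synthetic_fixtures** — deterministic toy proteomes and evidence tables
  with planted ground truth, so everything is testable offline.

## CLI

```sh
peplib simulate --seed 1 --out-dir fx          # synthetic fixture
peplib digest --fasta fx/proteome.fasta --out peptides.tsv
peplib index  --fasta fx/proteome.fasta --out index.tsv
peplib nsaf   --fasta fx/proteome.fasta --counts fx/spectral_counts.tsv --out nsaf.tsv
peplib ptm-filter --fasta fx/proteome.fasta --ptms fx/ptm_records.tsv --out-dir ptm/
peplib build --fasta fx/proteome.fasta \
             --counts fx/spectral_counts.tsv \
             --evidence fx/peptide_evidence.tsv \
             --ptms fx/ptm_records.tsv \
             --out-dir out/                    # full chain
```

All outputs are header-rowed TSV (plus FASTA); options can come from a YAML
config via `--config` (flags take precedence). Exit codes: 0 success,
1 input error, 2 internal error.

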