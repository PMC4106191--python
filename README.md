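# peptopo

Membrane-peptide topography toolkit for salt-bridge ("ion-lock") peptide
design and infrared structural analysis:

- **peptides** — sequence model, bundled lung-surfactant mimic fixtures, and
  ion-lock (Glu⁻/Lys⁺ at i, i+4) variant construction; FASTA I/O.
- **hydropathy** — 19-residue sliding-window whole-residue water→octanol
  hydropathy with an engaged/disengaged salt-bridge option; predicts
  transmembrane helix segments.
- **beta_pairing** — pairwise β-sheet pairing-energy scanning (parallel and
  antiparallel registers), ranked pairings, per-residue aggregation profiles,
  amyloid classification against a strict −29.0 threshold. Propensity tables
  are pluggable TSV inputs; only a clearly labelled toy table is bundled.
- **ftir** — amide-I spectral processing: two-column CSV/TSV and JCAMP-DX
  readers, reference subtraction, second-derivative band picking,
  Gaussian–Lorentzian band fitting with a linear baseline, secondary-structure
  fractions from class frequency windows, β-polymorph (fibril vs oligomer)
  classification, helix-length arithmetic.
- **orientation** — polarized-ATR dichroic ratio → order parameters → maximum
  helix tilt angle (thick-film model), with the forward model used as the
  generator/oracle.
- **hdx** — H/D exchange kinetics: amide II/I normalization and bounded
  multi-start fitting of first-order exchange compartments plus a
  non-exchanging plateau; unexchanged helical-residue arithmetic.
- **simulate** — deterministic synthetic-data generators (amide-I spectra,
  polarized pairs, HDX series) with machine-readable truth records.
- **pipeline** — per-peptide orchestration with a combined TSV report and a
  hydropathy-vs-pairing-energy table.

## Command line

All functionality is exposed through one entry point:

```bash
peptopo hydropathy --window 19 --lock 20:24 --engaged        # bundled fixtures
peptopo hydropathy --fasta peptides.fasta --window 19
peptopo betapair --min-len 4 --top 100 --table pasta.tsv
peptopo ftir fractions --spectrum S.csv --reference R.csv --region 1600:1715
peptopo orient --parallel P.csv --perpendicular Q.csv --band 1645:1662
peptopo hdx fit --series S.tsv --components 2
peptopo simulate spectrum --preset parallel_fibril --seed 1 --out out/
peptopo pipeline --config config.yaml --out report.tsv
```

The pipeline YAML lists peptides (bundled fixture ids, inline sequences, or
FASTA references) with optional per-stage inputs (`spectrum`, `reference`,
`polarized`, `hdx_series`, `lock`) and config-exposed thresholds
(`span_threshold`, `tilt_threshold_deg`, `helix_fraction_floor`, `window`).

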