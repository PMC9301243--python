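# flavomics

Suspect screening and differential analysis of flavonoid glycoconjugates
from high-resolution LC-ESI(+)-QTOF data, with a synthetic-data generator
for fully reproducible end-to-end testing.

The package implements:

* **Exact-mass arithmetic** (`flavomics.chem`) — molecular-formula parsing
  (including native-cation charges such as `C22H23O11+`), monoisotopic
  masses, `[M+H]+` / native-cation m/z (proton and electron masses applied
  correctly), signed ppm errors.
* **A flavonoid suspect library** (`flavomics.library`) — 11 aglycones in
  five families (anthocyanidin, flavone, isoflavone, pterocarpan,
  flavanone), five dehydrated glycosyl/acyl residues (Glc, GlcA, Mal, Fer,
  Cou), conjugate composition by pure residue addition, combinatorial
  decomposition of precursor masses at ppm tolerance, glycosylation-degree
  classification (Agly/Gly/GlyGly/GlyGlyGly + acylated) and RT-ordered
  Roman-numeral isomer indexing.  A packaged 46-compound table ships with
  the library.
* **Spectral annotation** (`flavomics.annotate`) — accurate-mass MS1
  screening, neutral-loss chain walking over every residue ordering
  (including combined acyl-glycan loss units), diagnostic ions (protonated
  aglycone / native cation, acyl-glycan fragments with charge retained on
  the glycan), confidence tiers `ms1_only` / `partial_ms2` / `full_chain`,
  and one-compound-per-feature assignment with runner-up reporting.
* **Peak-list I/O** (`flavomics.peaklists`) — MGF, a documented CSV dialect
  (`feature_id, precursor_mz, rt_min, ms2_mz|…, ms2_intensity|…,
  sample_id`) and centroided mzML (64/32-bit float arrays, optional zlib).
* **Synthetic data** (`flavomics.simulate`) — in-silico spectra
  (precursor + fragment ladder with configurable ppm jitter and fragment
  dropout) and log-normal intensity matrices over the 4 cultivars × 2
  tissues × 2 treatments × 3 biological replicates × 3 injections design,
  with tissue-level composition targets honoured by construction and
  per-compound treatment effects (log2 FC) as ground truth.
* **Statistics** (`flavomics.stats`) — family / glycosylation-degree
  relative abundances, leaf/root ratios, Welch (or Student) t-tests on log2
  intensities with fold-change regulation calls (up: FC > 2.5 & p < 0.05;
  down: FC < 0.4 & p < 0.05; the log2 gate is derived, not hard-coded),
  optional Benjamini–Hochberg adjustment, complete-linkage hierarchical
  clustering under Pearson distance (Newick export) and PCA on autoscaled
  data with an explained-variance report.

## Command line

```sh
flavomics simulate --seed 1 --out run/            # synthetic bundle + truth
flavomics annotate --spectra run/spectra.mgf --out run/
flavomics stats --intensities run/intensities.csv \
                --metadata run/sample_metadata.csv --out run/
flavomics all --seed 1 --out run/                 # the whole pipeline
```

All commands accept `--config config.yaml` (see `config.example.yaml` for
the commented template); CLI flags override file values.  Every run writes
`config.resolved.yaml` next to its outputs, and every table carries the
configuration hash and seed in a `#` header line, so a rerun with the same
configuration is byte-identical.

Simulation scenarios: `default` (composition targets only, no treatment
effects), `paper-like` (adds the published-style per-compound log2 FC
effects as ground truth) and `null` (no effects; type-I error checks).

## Library format

`flavomics.library.load_library` reads a TSV with columns
`peak, rt_min, name, aglycone, residues` (residues comma-separated, e.g.
`Fer,GlcA,GlcA`); `save_library` writes the same dialect.  Custom aglycones
and residues can be composed programmatically via `AglyconeRecord`,
`ResidueRecord` and `compose_compound`.
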