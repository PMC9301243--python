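# flavomics pipeline configuration (all keys optional; defaults shown).
# CLI flags override file values; every run writes config.resolved.yaml.

library: packaged          # "packaged" or a path to a compound TSV
spectra_path: null         # peak-list input for `annotate`
spectra_format: null       # mgf | csv | mzml (null: infer from suffix)
intensity_path: null       # sample x compound CSV for `stats`
metadata_path: null        # sample metadata CSV for `stats`

ms1_tol_ppm: 10.0          # accurate-mass gate for MS1 screening
frag_tol_mda: 5.0          # absolute MS/MS fragment tolerance (mDa)
rt_window: null            # optional hard RT gate in minutes (advisory if null)

p_cutoff: 0.05             # t-test significance gate
fc_up: 2.5                 # upregulated when FC > fc_up and p < p_cutoff
fc_down: 0.4               # downregulated when FC < fc_down and p < p_cutoff
equal_var: false           # false: Welch t-test; true: Student
average_injections: true   # average analytical injections per biological rep
fdr: false                 # also report Benjamini-Hochberg adjusted p-values

scenario: paper-like       # simulation preset: default | paper-like | null
seed: 0                    # seed for every source of randomness
ppm_jitter: 0.0            # precursor/fragment m/z jitter (ppm SD)
frag_dropout: 0.0          # per-fragment dropout probability

out_dir: flavomics_out
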