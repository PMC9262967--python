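# Search and reporting thresholds for stageglyco subcommands.
# All keys are optional; values below are the defaults.

precursor_tol_ppm: 10.0      # MS1 match tolerance
fragment_tol_ppm: 20.0       # MS2 / oxonium match tolerance
max_missed_cleavages: 2
max_dynamic_mods: 3          # oxidation + glyco remnants per peptide
min_fragment_matches: 6      # index hits required to become a candidate
top_peaks: 100               # peaks matched against the fragment index
coverage_fraction: 0.10      # matched intensity share must exceed this
fdr_level: 0.01              # PSM-level q-value cutoff
denoise_floor_fraction: 0.005  # drop peaks below 0.5% of base peak

# quantification / differential
presence_fraction: 0.75      # min share of non-reference channels quantified
diff_fdr_level: 0.01         # unpaired (BH-adjusted) significance
diff_p_level: 0.05           # paired-test significance
fold_change: 1.5
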