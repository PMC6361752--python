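# Annotated configuration for `zfqsar run`.
# Every key is optional; omitted keys fall back to the defaults shown.

# Inputs. Leave both unset to run on the packaged 19-cephalosporin study
# data (printed concentration table + curated pH-7 structures).
dose_response_csv: null     # CSV: drug_id, dose_mM, internal_conc_1e-5mM
structures_file: null       # name<TAB>SMILES (.smi) or SDF

# Train/test split. Either a fraction (training count rounds to the
# nearest integer: 19 compounds -> 15) or an explicit test-id list.
split_fraction: 0.8
test_ids: []                # e.g. [cefalexin, cefadroxil, cefotaxime, cefotiam]
split_seed: 0

# Descriptor stage.
descriptor_seed: 0          # conformer embedding seed
variance_floor: 1.0e-8      # prune columns with variance below this
dominance_ceiling: 0.9      # prune columns whose modal value covers > 90% of rows
dilution_factor: 1.0        # sample work-up dilution for unit conversion

# Genetic search (zfqsar.gfa.GFAConfig).
gfa:
  population_size: 100
  max_generations: 5000
  term_count_min: 2
  term_count_max: 4         # the packaged study has five descriptors; keep <= 5
  correlation_threshold: 0.95
  smoothing_d: 0.5          # Friedman LOF size penalty
  mutation_rate: 0.1
  crossover_rate: 0.9
  elitism_count: 1
  patience: 200             # early stop after this many stale generations; 0 = off
  seed: 0
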