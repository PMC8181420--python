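cohort:
  n_samples: 8
  n_sites: 200
  germline_rate: 0.45
  somatic_rate: 0.1
  artifact_rate: 0.05
  somatic_aaf_range:
  - 0.02
  - 0.35
  germline_aaf_center: 0.5
  depth_distribution:
  - 700.0
  - 0.3
  exonic_fraction: 0.85
  known_maf_distribution:
  - 0.9
  - 0.01
  - 0.5
  artifact_sample_fraction: 0.4
  seed: 821328062
amplicon:
  tissue_aaf: 0.5
  ctdna_fraction_pre: 0.01
  ctdna_fraction_post: 0.2
  depth_pre: 235000
  depth_post: 235000
  error_rate: 0.001
  mutant_base: T
  ref_base: C
  gene: SIM
  locus_id: sim_locus
  seed: 1529665511
ladder_pre:
  peak_orders:
  - 1
  - 2
  - 3
  - 4
  peak_centers:
  - 165.0
  - 380.0
  - 630.0
  - 870.0
  peak_widths:
  - 12.0
  - 22.0
  - 30.0
  - 38.0
  molar_amounts:
  - 1.0
  - 0.25
  - 0.08
  - 0.03
  long_tail_mass: 0.0
  long_tail_center: 1300.0
  long_tail_width: 250.0
  noise_sd: 0.05
  size_grid:
  - 25.0
  - 2000.0
  - 5.0
  seed: 745650761
ladder_post:
  peak_orders:
  - 1
  - 2
  - 3
  - 4
  peak_centers:
  - 165.0
  - 380.0
  - 630.0
  - 870.0
  peak_widths:
  - 12.0
  - 22.0
  - 30.0
  - 38.0
  molar_amounts:
  - 1.4
  - 0.65
  - 0.25
  - 0.12
  long_tail_mass: 40.0
  long_tail_center: 1300.0
  long_tail_width: 250.0
  noise_sd: 0.05
  size_grid:
  - 25.0
  - 2000.0
  - 5.0
  seed: 737436698
kinetics:
  n_patients: 6
  baseline_lognormal:
  - 1.0986122886681098
  - 0.35
  release_amplitude_lognormal:
  - 0.5877866649021191
  - 0.5
  release_scale: 1.0
  peak_time_range:
  - 60.0
  - 120.0
  timepoints:
  - 0
  - 10
  - 30
  - 60
  - 120
  noise_cv: 0.1
  seed: 494636353
thresholds:
  max_aaf: 0.35
  max_pop_maf: 0.01
  min_depth: 50
  max_recurrence: 0.25
max_order: 4
seed: 0
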