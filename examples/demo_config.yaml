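# Demonstration pipeline: histology -> CASA -> statistics on synthetic data.
out_dir: results/demo
seed: 1
stages: [histology, casa, stats]

histology_sim:
  n_tubules: 40
  radius_mean_um: 28.0
  p_vacuole_tubule: 0.15
n_sections_train: 2
n_sections_test: 2

track_sim:
  n_per_class:
    progressive: 40
    intermediate: 40
    hyperactivated: 40
    slow: 40
    weakly_motile: 40
timepoints_min: [10, 30, 60, 90, 120]

pheno_traits:
  - {trait_name: testis_weight, va: 0.7, ve: 0.3}
  - {trait_name: body_weight, va: 0.84, ve: 0.16, age_slope: 0.002}
  - {trait_name: vacuole_tubules, va: 0.35, ve: 0.65, missing_rate: 0.05}
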