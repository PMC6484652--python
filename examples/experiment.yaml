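# Two-hospital forecasting experiment: large frequent-visit source site,
# small sparse-visit target site sharing the outcome mechanism.
source_profile:
  name: UH
  n_patients: 600
  seed: 7
target_profile:
  name: SNH
  n_patients: 250
  visit_gap_median_days: 180
  n_visits_median: 4
  age_mean_sd: [60, 15]
  sex_female_prob: 0.806
  race_probs: {white: 0.124, african_american: 0.079, hispanic: 0.368, asian: 0.289, other: 0.140}
  med_propensity: {csDMARD: 0.789, biologic: 0.289, tofacitinib: 0.0, corticosteroid: 0.5}
  lab_missing_prob: {ESR: 0.4, CRP: 0.4}
  seed: 13
hyperparams:
  max_epochs: 40
  patience: 8
pis_repeats: 20
pis_groups: [CDAI, ESR, CRP]
tsne: true
seed: 5
out_dir: experiment_out
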