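# Study conditions for the analysis scripts: a 56-patient cohort with the
# cohort's class balance (13 relapse), three 8-colour tubes of 5,000 events,
# and the CD38 relapse signature planted by default.
seed: 1
cohort:
  n_patients: 56
  prevalence: 0.232142857
  events_per_tube: 5000
  effects: default
preprocess:
  subsample_n: 3000
validate:
  schemes:
    - {scheme: loocv}
    - {scheme: kfold, k: 4}
    - {scheme: kfold, k: 8}
  repeats: 20
  n_splits: 100
  rf: {n_runs: 100, n_trees: 50}
associate:
  marker: CD38
  levels: [15, 50, 85]
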