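# Example configuration: a 400-patient single-stratum cohort with a known
# prognostic CTC cutpoint planted at 0.7 cells/mL (hazard ratio 4 on DRFS),
# marker resolution 0.1 cells/mL, and a 500-iteration threshold search.
cohort:
  n_patients: 400
  prop_ilc: 1.0
  prop_neoadjuvant: 0.0
  marker_decimals: 1
  missing_rates: {}
  survival_model:
    drfs: {baseline_rate: 0.05, censor_low: 2.0, censor_high: 18.0}
    planted_cutpoint:
      marker: ctc
      threshold: 0.7
      hazard_ratio: 4.0
      endpoints: [drfs]
mccv:
  n_iterations: 500
  endpoint_policy: drfs_only
analysis:
  transform: log10p1
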