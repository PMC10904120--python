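# Example cvdsim CLI configuration.
# One file drives every command; CLI flags override these values.
# Treatment effect sizes are user-supplied placeholders: replace them
# with the evidence your analysis relies on before drawing conclusions.

seed: 1

synth:
  n: 5000
  cohort: out/cohort.csv
  followup: out/followup.csv       # optional: IPD sampled from `coefficients`
  followup_years: 10
  survey: out/survey.csv           # optional: EQ-5D survey records
  survey_n: 10000
  survey_noise_sd: 0.1
  reference: out/reference.csv     # optional: standardization weights
  # coefficients: path/to/true_equations.json   # default: packaged fixture

fit:
  cohort: out/cohort.csv
  followup: out/followup.csv
  out: out/fitted.json
  bootstrap: 0                     # >0 writes a PSA ensemble directory
  ensemble_dir: out/ensemble
  equations:
    - endpoint: mi
      population: no_cvd
      covariates: [male, smoking_current, ldl, hdl, sbp,
                   treated_hypertension, townsend_step]
    - endpoint: nonvascular_death
      population: no_cvd
      covariates: [male, smoking_current, townsend_step]

calibrate:
  cohort: out/cohort.csv
  followup: out/followup.csv
  coefficients: out/fitted.json
  out: out/calibrated.json
  horizon: 10
  fit_slope: false

validate:
  cohort: out/cohort.csv
  followup: out/followup.csv
  coefficients: out/calibrated.json
  out: out/validation.json
  horizon: 10
  horizons:                        # per-endpoint overrides
    diabetes: 8
  replicates: 10

simulate:
  cohort: out/cohort.csv
  coefficients: out/calibrated.json
  replicates: 500
  out: out/simulation

scenario:
  cohort: out/cohort.csv
  coefficients: out/calibrated.json
  replicates: 100
  out: out/scenario_contrast.csv
  rule:
    ten_year_risk_threshold: 10.0
    egfr_threshold: 60.0
  effect:                          # REQUIRED, placeholder values
    ldl_reduction_fraction: {atorva20: 0.40, atorva80: 0.50}
    rate_ratio_per_mmol:
      mi: 0.76
      stroke: 0.84
      crv: 0.76
      vascular_death: 0.88
  uptake: {1: 0.40, 2: 0.41, 3: 0.42, 4: 0.44, 5: 0.45}

psa:
  cohort: out/cohort.csv
  ensemble_dir: out/ensemble
  replicates: 50
  out: out/psa.json
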