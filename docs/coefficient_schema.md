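# Coefficient file schema

A coefficient set is a single JSON document. The `version` field is
mandatory (current: `1`). Example skeleton:

```json
{
  "version": 1,
  "registry_version": "1",
  "replicate_id": 0,
  "centring": {"age": 60.0, "ldl": 3.6, "hdl": 1.3, "hba1c": 36.0,
               "creatinine": 80.0, "sbp": 140.0, "dbp": 80.0},
  "equations": [
    {
      "endpoint": "mi",
      "population": "no_cvd",
      "baseline": {"log_hazard_intercept": -6.72, "age_slope": 0.07},
      "coefficients": {"male": 0.55, "ldl": 0.28, "mi_this_year": 0.0},
      "calibration": {"intercept_shift": 0.0, "slope_shift": 0.0}
    }
  ],
  "qol": {
    "intercept": 0.92,
    "coefficients": {"mi_year_of_event": -0.10, "mi_subsequent": -0.07},
    "bounds": [-0.594, 1.0]
  }
}
```

Rules:

- `endpoint` ∈ {mi, stroke, crv, cancer, diabetes, vascular_death,
  nonvascular_death}; `population` ∈ {no_cvd, cvd, pooled}. Every
  endpoint must resolve for both prevention populations, either through
  population-specific equations or a pooled one. Duplicate
  endpoint/population pairs are rejected.
- `baseline.log_hazard_intercept` is the log events/year at the centring
  age for the reference covariate pattern; `age_slope` is the Gompertz
  per-year-of-age increment. `calibration` shifts add to these.
- Coefficient keys must come from the shared covariate registry
  (`cvdsim.registry`): reference levels are female, white ethnicity,
  never-smoker, BMI 18.5–25, high physical activity, Townsend quintile
  1, no treatments or histories; continuous covariates are centred at
  the file's `centring` constants; `townsend_step` is linear per
  quintile step. Event-history terms: `mi_this_year`/`mi_prior_years`,
  `stroke_this_year`/`stroke_prior_years`, `crv_any`, `cancer_any`,
  `diabetes_first_10y`/`diabetes_after_10y`, `hba1c_nondiabetic`
  (HbA1c effect only while no diabetes is diagnosed).
- QoL coefficient keys use the same registry plus the utility-phase
  aliases `mi_year_of_event`/`mi_subsequent`,
  `stroke_year_of_event`/`stroke_subsequent`, and may include
  `age_centred`.
- `replicate_id` 0 marks the point estimate; k ≥ 1 marks bootstrap
  replicate k of a PSA ensemble.
- Unknown covariate names, non-numeric coefficients, missing
  equations or a missing/unsupported `version` are hard errors; a file
  never loads partially.

Serialization round-trips exactly (`write_coefficients` then
`read_coefficients` reproduces the set).
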