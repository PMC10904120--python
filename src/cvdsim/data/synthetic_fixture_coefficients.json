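{
 "centring": {
  "age": 60.0,
  "creatinine": 80.0,
  "dbp": 80.0,
  "hba1c": 36.0,
  "hdl": 1.3,
  "ldl": 3.6,
  "sbp": 140.0
 },
 "equations": [
  {
   "baseline": {
    "age_slope": 0.07,
    "log_hazard_intercept": -6.725433722188183
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "diabetes_after_10y": 0.75,
    "diabetes_first_10y": 0.5,
    "diet_unhealthy": 0.1,
    "hba1c_nondiabetic": 0.02,
    "hdl": -0.45,
    "ldl": 0.28,
    "male": 0.55,
    "pa_low": 0.15,
    "pa_missing": 0.1,
    "sbp": 0.01,
    "smoking_current": 0.6,
    "smoking_ex": 0.15,
    "stroke_prior_years": 0.2,
    "stroke_this_year": 0.3,
    "townsend_step": 0.05,
    "treated_hypertension": 0.25
   },
   "endpoint": "mi",
   "population": "no_cvd"
  },
  {
   "baseline": {
    "age_slope": 0.085,
    "log_hazard_intercept": -7.1308988302963465
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "diabetes_after_10y": 0.65,
    "diabetes_first_10y": 0.4,
    "diet_unhealthy": 0.08,
    "hba1c_nondiabetic": 0.015,
    "male": 0.25,
    "mi_prior_years": 0.45,
    "mi_this_year": 0.9,
    "pa_low": 0.12,
    "sbp": 0.012,
    "smoking_current": 0.55,
    "townsend_step": 0.13976194237515863,
    "treated_hypertension": 0.3
   },
   "endpoint": "stroke",
   "population": "no_cvd"
  },
  {
   "baseline": {
    "age_slope": 0.05,
    "log_hazard_intercept": -6.725433722188183
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "diabetes_after_10y": 0.6,
    "diabetes_first_10y": 0.4,
    "hba1c_nondiabetic": 0.015,
    "ldl": 0.3,
    "male": 0.6,
    "mi_prior_years": 0.5,
    "mi_this_year": 1.2,
    "smoking_current": 0.35,
    "treated_hypertension": 0.15
   },
   "endpoint": "crv",
   "population": "no_cvd"
  },
  {
   "baseline": {
    "age_slope": 0.105,
    "log_hazard_intercept": -7.600902459542082
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "cancer_any": 0.2,
    "crv_any": -0.25,
    "diabetes_after_10y": 0.8,
    "diabetes_first_10y": 0.5,
    "diet_unhealthy": 0.1,
    "hba1c_nondiabetic": 0.02,
    "male": 0.5,
    "mi_prior_years": 0.8,
    "mi_this_year": 2.0,
    "pa_low": 0.2,
    "sbp": 0.01,
    "smoking_current": 0.7,
    "stroke_prior_years": 0.9,
    "stroke_this_year": 1.9,
    "townsend_step": 0.13976194237515863
   },
   "endpoint": "vascular_death",
   "population": "no_cvd"
  },
  {
   "baseline": {
    "age_slope": 0.095,
    "log_hazard_intercept": -5.8781358618009785
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "cancer_any": 1.3,
    "diabetes_after_10y": 0.5,
    "diabetes_first_10y": 0.3,
    "male": 0.3,
    "pa_low": 0.25,
    "pa_missing": 0.15,
    "severe_mental_illness": 0.3,
    "smoking_current": 0.8,
    "smoking_ex": 0.2,
    "townsend_step": 0.13976194237515863
   },
   "endpoint": "nonvascular_death",
   "population": "no_cvd"
  },
  {
   "baseline": {
    "age_slope": 0.055,
    "log_hazard_intercept": -5.115995809754082
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "diabetes_after_10y": 0.6000000000000001,
    "diabetes_first_10y": 0.4,
    "diet_unhealthy": 0.08000000000000002,
    "hba1c_nondiabetic": 0.016,
    "hdl": -0.36000000000000004,
    "ldl": 0.22400000000000003,
    "male": 0.44000000000000006,
    "other_chd_history": 0.15,
    "pa_low": 0.12,
    "pa_missing": 0.08000000000000002,
    "sbp": 0.008,
    "smoking_current": 0.48,
    "smoking_ex": 0.12,
    "stroke_prior_years": 0.16000000000000003,
    "stroke_this_year": 0.24,
    "townsend_step": 0.04000000000000001,
    "treated_hypertension": 0.2
   },
   "endpoint": "mi",
   "population": "cvd"
  },
  {
   "baseline": {
    "age_slope": 0.07,
    "log_hazard_intercept": -5.521460917862246
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "diabetes_after_10y": 0.52,
    "diabetes_first_10y": 0.32000000000000006,
    "diet_unhealthy": 0.064,
    "hba1c_nondiabetic": 0.012,
    "male": 0.2,
    "mi_prior_years": 0.36000000000000004,
    "mi_this_year": 0.7200000000000001,
    "pa_low": 0.096,
    "sbp": 0.009600000000000001,
    "smoking_current": 0.44000000000000006,
    "townsend_step": 0.11180955390012691,
    "treated_hypertension": 0.24
   },
   "endpoint": "stroke",
   "population": "cvd"
  },
  {
   "baseline": {
    "age_slope": 0.04,
    "log_hazard_intercept": -5.115995809754082
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "diabetes_after_10y": 0.48,
    "diabetes_first_10y": 0.32000000000000006,
    "hba1c_nondiabetic": 0.012,
    "ldl": 0.24,
    "male": 0.48,
    "mi_prior_years": 0.4,
    "mi_this_year": 0.96,
    "smoking_current": 0.27999999999999997,
    "treated_hypertension": 0.12
   },
   "endpoint": "crv",
   "population": "cvd"
  },
  {
   "baseline": {
    "age_slope": 0.1,
    "log_hazard_intercept": -5.654992310486769
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "cancer_any": 0.16000000000000003,
    "crv_any": -0.25,
    "diabetes_after_10y": 0.6400000000000001,
    "diabetes_first_10y": 0.4,
    "diet_unhealthy": 0.08000000000000002,
    "hba1c_nondiabetic": 0.016,
    "male": 0.4,
    "mi_prior_years": 0.6400000000000001,
    "mi_this_year": 1.6,
    "pa_low": 0.16000000000000003,
    "pad_history": 0.2,
    "sbp": 0.008,
    "smoking_current": 0.5599999999999999,
    "stroke_prior_years": 0.7200000000000001,
    "stroke_this_year": 1.52,
    "townsend_step": 0.11180955390012691
   },
   "endpoint": "vascular_death",
   "population": "cvd"
  },
  {
   "baseline": {
    "age_slope": 0.095,
    "log_hazard_intercept": -5.572754212249797
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "cancer_any": 1.1700000000000002,
    "diabetes_after_10y": 0.45,
    "diabetes_first_10y": 0.27,
    "male": 0.27,
    "pa_low": 0.225,
    "pa_missing": 0.135,
    "severe_mental_illness": 0.27,
    "smoking_current": 0.7200000000000001,
    "smoking_ex": 0.18000000000000002,
    "townsend_step": 0.12578574813764276
   },
   "endpoint": "nonvascular_death",
   "population": "cvd"
  },
  {
   "baseline": {
    "age_slope": 0.055,
    "log_hazard_intercept": -5.298317366548036
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "bmi_30_35": 0.1,
    "bmi_35_40": 0.15,
    "bmi_40plus": 0.2,
    "male": 0.2,
    "smoking_current": 0.7,
    "smoking_ex": 0.2,
    "townsend_step": 0.03
   },
   "endpoint": "cancer",
   "population": "pooled"
  },
  {
   "baseline": {
    "age_slope": 0.02,
    "log_hazard_intercept": -5.521460917862246
   },
   "calibration": {
    "intercept_shift": 0.0,
    "slope_shift": 0.0
   },
   "coefficients": {
    "bmi_25_30": 0.5,
    "bmi_30_35": 1.0,
    "bmi_35_40": 1.4,
    "bmi_40plus": 1.8,
    "hba1c_nondiabetic": 0.1,
    "male": 0.2,
    "pa_low": 0.2,
    "smoking_current": 0.25,
    "townsend_step": 0.13976194237515863
   },
   "endpoint": "diabetes",
   "population": "pooled"
  }
 ],
 "qol": {
  "bounds": [
   -0.594,
   1.0
  ],
  "coefficients": {
   "age_centred": -0.0035,
   "bmi_40plus": -0.07,
   "cancer_any": -0.03,
   "diabetes_after_10y": -0.08,
   "diabetes_first_10y": -0.04,
   "male": 0.015,
   "mi_subsequent": -0.07,
   "mi_year_of_event": -0.1,
   "pa_low": -0.05,
   "pa_missing": -0.015,
   "severe_mental_illness": -0.1,
   "smoking_current": -0.04,
   "stroke_subsequent": -0.13,
   "stroke_year_of_event": -0.09,
   "townsend_step": -0.01
  },
  "intercept": 0.92
 },
 "registry_version": "1",
 "replicate_id": 0,
 "version": 1
}
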