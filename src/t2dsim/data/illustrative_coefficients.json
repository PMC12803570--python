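{
 "version": "illustrative-1 (synthetic coefficients for testing; not the published model values)",
 "ua_proxy_share": 0.0,
 "equations": [
  {
   "name": "mi",
   "kind": "event",
   "baseline_form": "exponential",
   "intercept": -8.2082,
   "coefficients": {
    "age": 0.025,
    "male": 0.35,
    "hba1c": 0.12,
    "sbp": 0.007,
    "ldl": 0.3,
    "hdl": -0.6,
    "smoking": 0.35,
    "hist_mi": 0.6,
    "hist_stroke": 0.2
   },
   "case_fatality": 0.15
  },
  {
   "name": "stroke",
   "kind": "event",
   "baseline_form": "exponential",
   "intercept": -9.8323,
   "coefficients": {
    "age": 0.04,
    "sbp": 0.012,
    "af": 0.6,
    "smoking": 0.3,
    "hist_stroke": 0.7,
    "hba1c": 0.08
   },
   "case_fatality": 0.15
  },
  {
   "name": "ihd",
   "kind": "event",
   "baseline_form": "exponential",
   "intercept": -6.8018,
   "coefficients": {
    "age": 0.02,
    "male": 0.3,
    "ldl": 0.25,
    "hdl": -0.5,
    "hba1c": 0.1,
    "smoking": 0.25,
    "hist_mi": 0.3
   },
   "requires_no_history": [
    "ihd"
   ]
  },
  {
   "name": "heart_failure",
   "kind": "event",
   "baseline_form": "weibull",
   "intercept": -9.8303,
   "coefficients": {
    "age": 0.05,
    "weight": 0.008,
    "egfr": -0.01,
    "af": 0.5,
    "hist_mi": 0.5,
    "hba1c": 0.08
   },
   "shape": 1.3,
   "requires_no_history": [
    "heart_failure"
   ]
  },
  {
   "name": "cv_death",
   "kind": "death",
   "baseline_form": "gompertz",
   "intercept": -9.8137,
   "coefficients": {
    "age": 0.07,
    "male": 0.2,
    "hist_mi": 0.6,
    "hist_stroke": 0.5,
    "hist_heart_failure": 0.8,
    "egfr": -0.012,
    "smoking": 0.3
   },
   "shape": 0.07
  },
  {
   "name": "noncv_death",
   "kind": "death",
   "baseline_form": "gompertz",
   "intercept": -10.0466,
   "coefficients": {
    "age": 0.08,
    "male": 0.25,
    "smoking": 0.5,
    "wbc": 0.05,
    "haemoglobin": -0.08
   },
   "shape": 0.09
  },
  {
   "name": "hba1c",
   "kind": "progression",
   "intercept": 0.219,
   "coefficients": {
    "current": 0.97,
    "diabetes_duration": 0.001
   }
  },
  {
   "name": "sbp",
   "kind": "progression",
   "intercept": 6.75,
   "coefficients": {
    "current": 0.95
   }
  },
  {
   "name": "weight",
   "kind": "progression",
   "intercept": 0.86,
   "coefficients": {
    "current": 0.99
   }
  },
  {
   "name": "hdl",
   "kind": "progression",
   "intercept": 0.022,
   "coefficients": {
    "current": 0.98
   }
  },
  {
   "name": "ldl",
   "kind": "progression",
   "intercept": 0.069,
   "coefficients": {
    "current": 0.97
   }
  },
  {
   "name": "heart_rate",
   "kind": "progression",
   "intercept": 2.16,
   "coefficients": {
    "current": 0.97
   }
  },
  {
   "name": "wbc",
   "kind": "progression",
   "intercept": 0.15,
   "coefficients": {
    "current": 0.98
   }
  },
  {
   "name": "haemoglobin",
   "kind": "progression",
   "intercept": 0.138,
   "coefficients": {
    "current": 0.99
   }
  },
  {
   "name": "egfr",
   "kind": "progression",
   "intercept": -0.9,
   "coefficients": {
    "current": 1.0
   }
  }
 ]
}
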