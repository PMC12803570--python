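{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "t2dsim coefficient set",
 "description": "Documentation-only schema for the coefficient JSON consumed by t2dsim.equations.load_coefficients. Validation is performed by the loader itself with named-field errors.",
 "type": "object",
 "required": ["equations"],
 "properties": {
  "version": {"type": "string"},
  "ua_proxy_share": {
   "type": "number", "minimum": 0, "maximum": 1,
   "description": "Probability that an ischemic-heart-disease event also registers an unstable-angina hospitalization (MACE-4 proxy); 0 disables it."
  },
  "equations": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["name", "kind"],
    "properties": {
     "name": {"type": "string", "description": "Endpoint name (event/death) or risk-factor name (progression)."},
     "kind": {"enum": ["event", "death", "progression"]},
     "baseline_form": {"enum": ["exponential", "weibull", "gompertz", "logistic"]},
     "shape": {"type": "number", "exclusiveMinimum": 0, "description": "Weibull/Gompertz shape; baseline integrated on the diabetes-duration timescale."},
     "intercept": {"type": "number"},
     "coefficients": {
      "type": "object",
      "additionalProperties": {"type": "number"},
      "description": "Covariate name -> per-unit log-hazard (or linear-predictor) weight. Names must resolve to a risk factor, demographic (age, male, diabetes_duration, height), hist_<event> flag, or 'current' (progression only)."
     },
     "requires_no_history": {
      "type": "array", "items": {"type": "string"},
      "description": "History flags that exclude the equation (first-event-only endpoints)."
     },
     "case_fatality": {"type": "number", "minimum": 0, "maximum": 1}
    }
   }
  }
 }
}
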