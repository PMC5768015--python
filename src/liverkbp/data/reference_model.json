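{
  "format": "liverkbp-model",
  "version": 1,
  "organs": [
    {"organ": "liver_gtv", "metric": {"kind": "volume_at_dose", "dose_gy": 5.0}, "model": {"type": "linear", "slope": 29.49, "intercept": 43.19, "shift": 0.0}, "unit": "%", "priority": "high", "compromise": true},
    {"organ": "liver_gtv", "metric": {"kind": "volume_at_dose", "dose_gy": 10.0}, "model": {"type": "linear", "slope": 27.26, "intercept": 30.62, "shift": 0.0}, "unit": "%", "priority": "high", "compromise": true},
    {"organ": "liver_gtv", "metric": {"kind": "volume_at_dose", "dose_gy": 20.0}, "model": {"type": "linear", "slope": 38.81, "intercept": 8.22, "shift": 0.0}, "unit": "%", "priority": "high", "compromise": true},
    {"organ": "liver_gtv", "metric": {"kind": "volume_at_dose", "dose_gy": 30.0}, "model": {"type": "linear", "slope": 41.52, "intercept": 3.15, "shift": 0.0}, "unit": "%", "priority": "high", "compromise": true},
    {"organ": "left_kidney", "metric": {"kind": "mean"}, "model": {"type": "linear", "slope": 462.0, "intercept": 211.0, "shift": 0.0}, "unit": "cGy", "priority": "high", "compromise": true},
    {"organ": "right_kidney", "metric": {"kind": "mean"}, "model": {"type": "linear", "slope": 1465.0, "intercept": 380.0, "shift": 0.0}, "unit": "cGy", "priority": "high", "compromise": true},
    {"organ": "spinal_cord_prv5", "metric": {"kind": "max"}, "model": {"type": "linear", "slope": 2005.0, "intercept": 1990.0, "shift": 0.0}, "unit": "cGy", "priority": "low", "compromise": true},
    {"organ": "stomach", "metric": {"kind": "volume_at_dose", "dose_gy": 20.0}, "model": {"type": "constant", "value": 15.0}, "unit": "%", "priority": "low", "compromise": true},
    {"organ": "small_bowel", "metric": {"kind": "volume_at_dose", "dose_gy": 15.0}, "model": {"type": "constant", "value": 35.0}, "unit": "%", "priority": "low", "compromise": true},
    {"organ": "heart", "metric": {"kind": "mean"}, "model": {"type": "constant", "value": 630.0}, "unit": "cGy", "priority": "low", "compromise": true},
    {"organ": "esophagus", "metric": {"kind": "max"}, "model": {"type": "constant", "value": 3863.0}, "unit": "cGy", "priority": "low", "compromise": true}
  ],
  "general_settings": {
    "tuning_balance_pct": 7.0,
    "dose_falloff_margin_cm": 2.6,
    "hotspot_max_goal_pct": 106.0,
    "use_coldspot_rois": true
  },
  "provenance": {
    "source": "published reference coefficients (liver lines carry the 95% coverage shift already applied)",
    "cohort_size": 50,
    "coverage_quantile": 0.05
  }
}
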