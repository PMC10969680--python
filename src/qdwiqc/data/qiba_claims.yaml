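# QIBA DWI profile claims for phantom ADC performance metrics.
# cmp semantics follow the printed comparators exactly (le passes at the
# boundary, lt does not).  ci_within requires the whole confidence
# interval inside [lo, hi].
profile: qiba_dwi
claims:
  - metric: adc_bias_pct
    cmp: abs_le
    threshold: 3.6
    units: "%"
    description: "ADC bias of the central (0% PVP) vial"
  - metric: rc_short_term
    cmp: lt
    threshold: 15.0
    units: "um^2/s"
    description: "short-term repeatability coefficient"
  - metric: wcv_short_term_pct
    cmp: le
    threshold: 0.5
    units: "%"
    description: "short-term within-subject CV"
  - metric: rc_long_term
    cmp: lt
    threshold: 65.0
    units: "um^2/s"
    description: "long-term repeatability coefficient"
  - metric: wcv_long_term_pct
    cmp: lt
    threshold: 2.2
    units: "%"
    description: "long-term within-subject CV"
  - metric: linearity_r_squared
    cmp: gt
    threshold: 0.90
    units: ""
    description: "R^2 of measured-vs-true ADC linear fit"
  - metric: linearity_slope_ci
    cmp: ci_within
    lo: 0.95
    hi: 1.05
    units: ""
    description: "95% CI of linearity slope"
  - metric: bvalue_dependence_pct
    cmp: le
    threshold: 2.0
    units: "%"
    applicability: "requires >= 3 b-values"
    description: "max b-value dependence, central vial"
  - metric: random_error_pct
    cmp: le
    threshold: 2.0
    units: "%"
    description: "random measurement error, central vial"
  - metric: snr_b0
    cmp: ge
    threshold: 45.0
    units: ""
    description: "difference-method SNR at b = 0"
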