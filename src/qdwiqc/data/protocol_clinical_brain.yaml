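# Tiered clinical brain DWI protocol specification.  Tiers are encoded
# in nested form (ideal implies target implies acceptable); where the
# printed ranges are non-nested (TR, slice thickness, parallel factor)
# the lower tiers keep only the outer bound so that exceeding a tier
# never demotes a parameter.
profile: clinical_brain
parameters:
  - parameter: n_bvalues
    ideal: {min: 4}
    target: {min: 2}
    acceptable: {min: 2}
  - parameter: highest_b
    ideal: {min: 1000}
    target: {min: 1000}
    acceptable: {min: 850}
  - parameter: tr_ms
    ideal: {min_exclusive: 5000}
    target: {min: 3000}
    acceptable: {min: 3000}
  - parameter: te_ms
    ideal: {max_exclusive: 60}
    target: {max_exclusive: 60}
    acceptable: {max_exclusive: 120}
  - parameter: slice_thickness_mm
    ideal: {max_exclusive: 4}
    target: {max: 5}
    acceptable: {max: 5}
  - parameter: gap_mm
    ideal: {max: 1}
    target: {max: 1}
    acceptable: {max: 2}
  - parameter: fov_mm
    ideal: {min: 220, max: 240}
    target: {min: 220, max: 240}
    acceptable: {min: 220, max: 240}
  - parameter: matrix_freq
    ideal: {min: 160, max: 256}
    target: {min: 160, max: 256}
    acceptable: {min: 128}
  - parameter: nex
    ideal: {min: 2}
    target: {min: 2}
    acceptable: {min: 1}
  - parameter: half_scan_factor
    ideal: {min_exclusive: 0.65}
    target: {min_exclusive: 0.65}
    acceptable: {min_exclusive: 0.65}
  - parameter: parallel_factor
    ideal: {min: 2, max: 3}
    target: {min: 2, max: 3}
    acceptable: {min: 2, max: 3}
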