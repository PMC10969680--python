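# Phantom-validation acquisition protocol (single-tier: every parameter
# must match).  "TE shortest" is operationalised as TE < 60 ms, the
# regime every conforming scan in the validation study satisfied.
profile: qiba_phantom
parameters:
  - parameter: b_values
    acceptable: {equals: [0, 500, 1000, 1500, 2000]}
  - parameter: tr_ms
    acceptable: {equals: 8000}
  - parameter: te_ms
    acceptable: {max_exclusive: 60}
  - parameter: matrix
    acceptable: {equals: [128, 128]}
  - parameter: fov_mm
    acceptable: {equals: 220}
  - parameter: slice_thickness_mm
    acceptable: {equals: 4}
  - parameter: gap_mm
    acceptable: {equals: 1}
  - parameter: nex
    acceptable: {equals: 2}
  - parameter: half_scan_factor
    acceptable: {min: 0.75}
  - parameter: parallel_factor
    acceptable: {equals: 2}
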