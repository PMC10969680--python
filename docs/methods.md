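# Methods

## Signal model and units

Vial (and tissue) signal follows the mono-exponential diffusion model
`S(b) = S0 · exp(−b · ADC)` with the b-value in s/mm² and the ADC in
mm²/s. The package stores ADC in µm²/s everywhere (1 × 10⁻³ mm²/s =
1000 µm²/s), so the exponent uses `ADC · 1e−6`; this matches the unit
the patient tables are reported in while keeping the b·ADC product
dimensionless, and confines the 10⁶ conversion to two lines of code.
Multi-compartment behaviour (IVIM perfusion, kurtosis) is deliberately
out of scope: the phantom vials and the QC claims are defined on the
mono-exponential model.

## Phantom simulator

The synthetic phantom is a set of non-overlapping cylindrical vials on
a voxel grid, each with a label, a radius in mm, an `S0`, and a true
ADC. Only the central 0 %-PVP (pure water) vial has a
reference-anchored truth, 1100 µm²/s; the other vials emulate
increasing PVP concentration with a monotone-decreasing ladder of free
configuration values (defaults 1000 → 130 µm²/s). All metrics are
defined per-vial, so the exact ladder values only set the lever arm of
the linearity fit.

Noise is Rician, the single-coil magnitude-MRI convention: two
independent Gaussian channels of standard deviation σ are added and
the magnitude `sqrt((S+n₁)² + n₂²)` taken; NEX n averages n
independent magnitude images. The helper `sigma_for_snr` inverts the
difference-method SNR relation `SNR ≈ S0·sqrt(π/2)/σ_eff`,
`σ_eff = σ/sqrt(NEX)`, so simulations can be pinned to a target b = 0
SNR. The simulator does not model EPI artifacts (ghosting,
susceptibility distortion), coil sensitivity profiles, gradient
nonlinearity or temperature drift; passing tests therefore validate
the estimator chain and its statistics, not robustness to structured
scanner artifacts.

Repeated-exam sessions optionally apply a multiplicative `S0` drift
between repeats (`inter_exam_cv`), emulating scanner gain instability;
with it at zero and no noise, repeats are bit-identical.

Two stock layouts are provided: a 13-vial demo on a 128×128 grid
(1.72 mm voxels, the protocol's FOV/matrix ratio) and a compact 5-vial
layout on a 64×64 grid with 5 slices used for Monte-Carlo work. The
5-slice VOI (≈560 voxels for a 10 mm-radius vial) mirrors the fact
that real phantom VOIs span many slices; it keeps the sampling error
of a 4-repeat wCV estimate comfortably below the 0.5 % claim at
b0 SNR ≈ 100, which a single-slice VOI would not.

## Patient-cohort generator

Longitudinal tissue-ROI observations are generated hierarchically:
each patient draws a true tissue mean from the population mean with a
between-subject CV (default 5 %), and each scan observes that mean
perturbed by the within-subject CV (default 2 %, the repeatability
regime reported for healthy white matter and CSF). Defaults are
white matter ≈ 800 µm²/s and CSF ≈ 3000 µm²/s, 14 patients × 2 scans.
The generator emits the same CSV schema the patient-QA stage consumes,
because in practice the computable surface starts at radiologist-drawn
ROI statistics, not raw images.

## ADC fitting

* `loglinear`: unweighted OLS of ln S on b over all usable b-points.
  The model names no weighting; unweighted OLS is the simplest
  defensible choice and is isolated behind `FitOptions` so a
  variance-weighted variant could be swapped in. Voxels drop
  individual b-points at or below `min_signal` (noise floor) rather
  than being discarded; fewer than two usable points gives NaN, never
  an exception.
* `two_point`: the closed form `ln(S_low/S_high)/(b_high−b_low)` using
  the lowest and highest b-values, mirroring clinical b = 0/1000
  usage. Negative ADCs under noise are returned as-is.

Both are exact (≤1e−10 relative) on noiseless mono-exponential input,
and identical there, which the tests exploit as a dual-route check.
The voxelwise map fit groups voxels by usable-point pattern and solves
one vectorised least-squares problem per pattern.

## VOI statistics

A voxel belongs to a circular ROI iff its center lies strictly inside
the circle — unambiguous, and boundary ties are measure-zero for
generic centers. Patient-style ROIs are single-slice circles
(20 mm white matter, 10 mm CSF, drawn on the b = 1000 image and
transferred to the ADC map at identical indices — no resampling);
phantom VOIs are the full multi-slice vial footprint, which shares the
simulator's inclusion rule and therefore contains no partial-volume
voxels. Statistics use the sample SD (n−1) since downstream RC/wCV
treat them as variance estimates; NaN voxels are excluded from the
count.

## Performance metrics

* **%bias** = 100·(μ − DC_true)/DC_true with μ the VOI-mean ADC.
* **Repeatability**: σ_w is the square root of the *unweighted* mean of
  within-group sample variances (groups = vials or patients), the
  standard pooled within-subject estimator; RC = 2.77·σ_w uses the
  profile's printed constant (not 1.96·√2 = 2.7719) so published
  tables are reproduced exactly; wCV = 100·σ_w/μ with μ the grand mean
  of the contributing observations.
* **Linearity**: OLS of VOI means on vial truths; R² from the residual
  sum of squares; 95 % slope CI via the t quantile with n−2 df,
  degenerate at the slope when the fit is exact.
* **b-value dependence**: for each nonzero b, a two-point (b_min, b)
  ADC map is computed and its central-vial VOI mean taken; the metric
  is the maximum relative deviation of these from their average. With
  fewer than two nonzero b-values (the clinical protocol) the metric
  is not evaluable and reported NA rather than failed.
* **Random measurement error** = 100·σ/μ of the central-vial VOI on a
  single ADC map, i.e. the *spatial* SD reading. This is a design
  choice where the definition is ambiguous (the σ could also be read
  as a repeat-based SD); it is isolated in one function so it can be
  swapped. Note its consequence: per-voxel ADC noise at b0 SNR ≈ 100
  is ≈4–5 % at this voxel size, so under that noise level the
  spatial-SD reading exceeds the 2 % claim even while bias, wCV and
  SNR pass comfortably; at SNR ≈ 300 it passes at ≈1.5 %. Vendor QC
  pipelines that report sub-2 % values at moderate SNR are likely
  computing a repeat-based or smoothed σ.
* **SNR**: noise image `|rep1 − rep2|/√2` from two repeated b = 0
  volumes; SNR is the ratio of in-mask spatial means of signal and
  noise images. Zero noise (the noiseless limit) is reported
  not-evaluable rather than infinite.

Reports round half-up to one decimal for display; full precision is
kept internally.

## Conformance engine

Claims and protocol tiers are YAML data, not code. Claim comparators
follow the printed boundary semantics exactly (`wCV ≤ 0.5` passes at
0.5; `RC < 15` fails at 15); the linearity claim applies to the whole
95 % CI of the slope. A metric with no value (NA) or no matching
claim is not-evaluable and never fails a report.

Protocol tiers are graded ideal → target → acceptable;
non-conformant if even acceptable fails, unknown (and overall
not-evaluable) if the parameter is missing. The shipped clinical
tiers are normalised to nested form — where the printed specification
is non-nested (TR ideal > 5000 ms vs target 3000–5000 ms; slice
thickness ideal < 4 mm vs target 4–5 mm; parallel factor ideal 2–3 vs
target 2) the lower tiers keep only the outer bound, so exceeding a
tier never demotes a parameter; the grader enforces this nesting at
evaluation time. "TE shortest" is encoded as TE < 60 ms, the regime
conforming validation scans satisfy. The half-scan factor has no
separate ideal tier and uses the target rule. Documented acquisition
deviations (e.g. NEX 1 on a particular scanner) can be recorded as
waivers: reported, not failed.

## Patient QA

Scorecards carry seven artifact items (low SNR, ghosting/parallel
imaging, spatial distortion, eddy currents, fat suppression, motion,
Nyquist ghost) on the 1/2/3 = unacceptable/acceptable/ideal scale;
aggregation is per-scanner mean ± sample SD per item with a flag if
any scan scored 1. Repeatability groups scans by patient within a
scanner (patients with ≥2 scans; none ⇒ not evaluable);
reproducibility pools all of a scanner's scans as one group, in which
case σ_w reduces to the plain SD across scans. CSF VOI means are
compared with the experimental ADC of water at 37 °C, 3037.7 µm²/s,
as absolute differences.

## Problem sizes and numerical choices

Monte-Carlo checks run on the 5-vial 64×64×5 layout (≈0.1 s per
4-repeat exam set): 100 seeds for the Rician claim-regime study and
500 seeds for cohort wCV recovery, sizes at which the empirical
distributions are stable (the 200-replicate pilot for the wCV upper
tail matched the 100-seed runs). The wCV estimator pooled from
14 patients × 2 scans is chi-distributed with ≈19 % relative SD, so
individual cohort estimates scatter widely around 2 %; the recovery
check therefore tests that the seed distribution covers the truth and
that its mean sits at the expected c₄ ≈ 0.982 shrinkage, not that
every seed lands near 2 %.

Determinism: every simulation takes a seed (or an inherited
generator), and pipeline reports embed the seed plus a hash of the
scientific configuration; fixed seed ⇒ byte-identical reports.

## Known limitations

No EPI-artifact or B0/B1 field modelling; single-slice circular ROIs
only (no freehand or spherical VOIs); no noise-floor correction in the
fits; no cross-site reproducibility statistic (RDC); no confidence
intervals on wCV; DICOM ingestion is out of scope (NIfTI + JSON
sidecar is the exam container).
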