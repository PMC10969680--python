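"""Voxelwise ADC map fitting.

Two estimators are provided, matching the two protocols the package
validates:

* ``loglinear`` — unweighted ordinary least squares of ``ln S`` on b
  across all usable b-values (multi-b phantom protocol); the slope is
  ``-ADC`` in mm^2/s.
* ``two_point`` — closed-form mono-exponential fit from the lowest and
  highest b-values, ``ADC = ln(S_low / S_high) / (b_high - b_low)``
  (two-b clinical protocol).

Both are exact on noiseless mono-exponential data.  ADC is returned in
um^2/s (1e-3 mm^2/s = 1000 um^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import DWISeries

__all__ = ["FitOptions", "ADCMap", "fit_adc_loglinear", "fit_adc_twopoint",
           "compute_adc_map"]

_MM2_TO_UM2 = 1e6  # mm^2/s -> um^2/s


@dataclass(frozen=True)
class FitOptions:
    """Options for voxelwise ADC fitting.

    ``min_signal`` drops individual b-points whose signal is at or below
    the threshold (noise floor) rather than dropping the voxel;
    ``require_n_points`` is the minimum number of surviving b-points for
    a fit (voxels below it become NaN).
    """

    method: str = "loglinear"  # loglinear | two_point
    min_signal: float = 0.0
    require_n_points: int = 2

    def __post_init__(self) -> None:
        if self.method not in ("loglinear", "two_point"):
            raise ValueError(f"unknown fit method {self.method!r}")
        if self.min_signal < 0:
            raise ValueError("min_signal must be >= 0")
        if self.require_n_points < 2:
            raise ValueError("require_n_points must be >= 2")


@dataclass
class ADCMap:
    """Voxelwise ADC map (um^2/s) with the b=0 intercept map."""

    values: np.ndarray  # 3-D, NaN where unfittable
    s0_map: np.ndarray
    method: str
    b_values: tuple[float, ...]
    exam_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.s0_map = np.asarray(self.s0_map, dtype=float)
        if self.values.shape != self.s0_map.shape:
            raise ValueError("values and s0_map shapes differ")


def fit_adc_loglinear(signals, b_values, min_signal: float = 0.0):
    """OLS fit of ln(S) against b for one voxel.

    Returns ``(adc_um2s, s0)``; ``(nan, nan)`` when fewer than two
    b-points have signal above ``min_signal``.
    """
    s = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    usable = np.isfinite(s) & (s > min_signal) & (s > 0)
    if usable.sum() < 2:
        return float("nan"), float("nan")
    x, y = b[usable], np.log(s[usable])
    slope, intercept = np.polyfit(x, y, 1)
    return float(-slope * _MM2_TO_UM2), float(np.exp(intercept))


def fit_adc_twopoint(s_low, s_high, b_low, b_high):
    """Closed-form two-point mono-exponential ADC (um^2/s).

    Negative results are possible under noise (S rising with b) and are
    returned as-is for the caller to flag.
    """
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    s_low = float(s_low)
    s_high = float(s_high)
    if not (s_low > 0 and s_high > 0):
        return float("nan")
    return float(np.log(s_low / s_high) / (b_high - b_low) * _MM2_TO_UM2)


def compute_adc_map(series: DWISeries, options: FitOptions | None = None
                    ) -> ADCMap:
    """Fit an ADC map over every voxel of a DWI exam.

    The log-linear route is fully vectorised: voxels sharing the same
    usable-point pattern are fitted in one least-squares call.  Voxels
    where the fit is impossible are NaN in both output maps.
    """
    options = options or FitOptions()
    b = np.asarray(series.params.b_values, dtype=float)
    if len(b) < 2:
        raise ValueError("ADC fitting needs at least 2 b-values")
    sig = series.signal
    spatial = sig.shape[:3]
    flat = sig.reshape(-1, len(b))

    if options.method == "two_point":
        i_lo, i_hi = 0, len(b) - 1
        s_lo, s_hi = flat[:, i_lo], flat[:, i_hi]
        ok = (s_lo > options.min_signal) & (s_hi > options.min_signal) \
            & (s_lo > 0) & (s_hi > 0)
        adc = np.full(flat.shape[0], np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            adc[ok] = (np.log(s_lo[ok] / s_hi[ok])
                       / (b[i_hi] - b[i_lo]) * _MM2_TO_UM2)
        s0 = np.where(ok, s_lo, np.nan)
        used = (b[i_lo], b[i_hi])
        return ADCMap(adc.reshape(spatial), s0.reshape(spatial),
                      "two_point", used, exam_id=series.exam_id)

    usable = np.isfinite(flat) & (flat > options.min_signal) & (flat > 0)
    enough = usable.sum(axis=1) >= max(options.require_n_points, 2)
    adc = np.full(flat.shape[0], np.nan)
    s0 = np.full(flat.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(usable, np.log(np.where(usable, flat, 1.0)), 0.0)
    # group voxels by usable-point pattern; each pattern is one lstsq
    patterns = np.packbits(usable[enough], axis=1, bitorder="little")
    idx_enough = np.flatnonzero(enough)
    keys = patterns.view([("", patterns.dtype)] * patterns.shape[1]).ravel()
    for key in np.unique(keys):
        sel = idx_enough[keys == key]
        pat = usable[sel[0]]
        x = b[pat]
        design = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(design, logs[sel][:, pat].T, rcond=None)
        adc[sel] = -coef[0] * _MM2_TO_UM2
        s0[sel] = np.exp(coef[1])
    return ADCMap(adc.reshape(spatial), s0.reshape(spatial),
                  "loglinear", tuple(b), exam_id=series.exam_id)
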