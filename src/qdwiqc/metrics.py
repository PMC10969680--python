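"""Quantitative DWI performance metrics.

Implements the QIBA-profile performance metrics for ADC measurement:

* **ADC bias** — ``mu - DC_true`` and its percentage of DC_true, with
  ``mu`` the VOI-mean ADC and ``DC_true`` the vial's ground truth.
* **Repeatability** — pooled within-subject SD ``sigma_w`` (square root
  of the unweighted mean of within-group sample variances), the
  repeatability coefficient ``RC = 2.77 * sigma_w`` and the
  within-subject coefficient of variation ``wCV = 100 * sigma_w / mu``.
  2.77 is the profile's printed constant (1.96 * sqrt(2) rounded).
* **Linearity** — OLS of measured VOI means on ground truth across
  vials, with an R^2 and a 95% t-based confidence interval on the slope.
* **b-value dependence** — maximum relative deviation of two-point
  (b_min, b) ADC estimates from their average; not evaluable with fewer
  than two nonzero b-values.
* **Random measurement error** — ``100 * sigma / mu`` from the spatial
  VOI statistics of a single ADC map (the within-VOI spatial SD reading;
  see docs/methods.md).
* **SNR (difference method)** — two repeated b=0 acquisitions form a
  noise image ``|rep1 - rep2| / sqrt(2)``; SNR is the ratio of in-ROI
  spatial means of the signal and noise images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .roi import VOIStats

__all__ = [
    "RepeatedMeasurements", "MetricResult", "LinearityFit",
    "RepeatabilityResult", "adc_bias", "repeatability",
    "rc_wcv_from_summary", "linearity", "bvalue_dependence",
    "random_error", "make_noise_image", "snr", "round1",
    "RC_COEFFICIENT",
]

#: multiplier turning sigma_w into the repeatability coefficient
RC_COEFFICIENT = 2.77


def round1(x: float) -> float:
    """Round half-up to one decimal, the report display convention."""
    if not np.isfinite(x):
        return float(x)
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"),
                                                  rounding=ROUND_HALF_UP))


@dataclass
class RepeatedMeasurements:
    """Grouped repeated observations: group id -> list of values.

    A group is a vial (phantom) or a patient (clinical); values are VOI
    mean ADCs in um^2/s.  ``term`` records whether the repeats are
    intra-session (short_term) or multiday (long_term).
    """

    groups: dict[str, list[float]]
    term: str = "short_term"

    def __post_init__(self) -> None:
        if self.term not in ("short_term", "long_term"):
            raise ValueError(f"unknown term {self.term!r}")
        for gid, vals in self.groups.items():
            if any(v <= 0 for v in vals):
                raise ValueError(f"group {gid!r} has nonpositive values")


@dataclass(frozen=True)
class MetricResult:
    """One computed metric with its claim verdict.

    ``passed`` is tri-state: True / False / None (not evaluable, e.g.
    b-value dependence under a two-b protocol, or no claim configured).
    """

    name: str
    value: float | None
    units: str = ""
    passed: bool | None = None
    claim: str = ""
    detail: dict = field(default_factory=dict)


@dataclass(frozen=True)
class LinearityFit:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    n: int

    def __post_init__(self) -> None:
        lo, hi = self.slope_ci
        if not (lo <= self.slope <= hi):
            raise ValueError("slope must lie inside its CI")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


@dataclass(frozen=True)
class RepeatabilityResult:
    sigma_w: float
    rc: float
    wcv_percent: float
    grand_mean: float
    n_groups: int
    n_observations: int


def adc_bias(mu: float, dc_true: float) -> tuple[float, float]:
    """ADC bias (um^2/s) and percent bias relative to ground truth."""
    if dc_true <= 0:
        raise ValueError("dc_true must be > 0")
    bias = mu - dc_true
    return bias, 100.0 * bias / dc_true


def repeatability(meas: RepeatedMeasurements) -> RepeatabilityResult:
    """Pooled within-group repeatability: sigma_w, RC and wCV.

    sigma_w^2 is the unweighted mean of within-group sample variances
    (each with its n-1 denominator) over groups with >= 2 observations;
    the grand mean pools all observations from those groups.
    """
    variances = []
    values = []
    for gid, vals in meas.groups.items():
        if len(vals) >= 2:
            variances.append(np.var(vals, ddof=1))
            values.extend(vals)
    if not variances:
        raise ValueError("no group has >= 2 observations")
    sigma_w = float(np.sqrt(np.mean(variances)))
    mu = float(np.mean(values))
    return RepeatabilityResult(
        sigma_w=sigma_w,
        rc=RC_COEFFICIENT * sigma_w,
        wcv_percent=100.0 * sigma_w / mu,
        grand_mean=mu,
        n_groups=len(variances),
        n_observations=len(values),
    )


def rc_wcv_from_summary(mean: float, sd: float) -> tuple[float, float]:
    """RC and wCV recomputed from a published mean and within-subject SD.

    Applies the same identities the full estimator obeys:
    RC = 2.77 * sd and wCV = 100 * sd / mean.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return RC_COEFFICIENT * sd, 100.0 * sd / mean


def linearity(points) -> LinearityFit:
    """OLS of measured VOI-mean ADC on ground-truth ADC across vials.

    ``points`` is a sequence of (dc_true, mu) pairs; needs >= 3 distinct
    ground-truth values.  The slope CI uses the t quantile with n-2
    degrees of freedom at 95%.
    """
    pts = [(float(x), float(y)) for x, y in points]
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if len(pts) < 3 or len(np.unique(x)) < 3:
        raise ValueError("linearity needs >= 3 distinct ground-truth values")
    n = len(pts)
    res = stats.linregress(x, y)
    slope, intercept = float(res.slope), float(res.intercept)
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    if ss_res <= 0:
        ci = (slope, slope)  # exact fit: degenerate CI
    else:
        tq = stats.t.ppf(0.975, n - 2)
        half = tq * res.stderr
        ci = (slope - half, slope + half)
    return LinearityFit(slope=slope, intercept=intercept, r_squared=r2,
                        slope_ci=ci, n=n)


def bvalue_dependence(per_b_adcs: dict[float, float]) -> float | None:
    """Max relative deviation (%) of per-b two-point ADCs from their mean.

    ``per_b_adcs`` maps each nonzero b-value to the VOI-mean ADC of the
    (b_min, b) two-point fit.  Returns None (not evaluable) with fewer
    than two entries — the case of a two-b clinical protocol.
    """
    if len(per_b_adcs) < 2:
        return None
    vals = np.array(list(per_b_adcs.values()), dtype=float)
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mean per-b ADC is zero")
    return float(100.0 * np.max(np.abs(vals - mean)) / abs(mean))


def random_error(voi: VOIStats) -> float:
    """Random measurement error: 100 * sigma / mu of the ADC-map VOI."""
    if voi.mean <= 0:
        raise ValueError("VOI mean must be > 0")
    return 100.0 * voi.sd / voi.mean


def make_noise_image(b0_rep1: np.ndarray, b0_rep2: np.ndarray) -> np.ndarray:
    """Difference-method noise image from two repeated b=0 volumes."""
    a = np.asarray(b0_rep1, dtype=float)
    b = np.asarray(b0_rep2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("repeat volumes must share a shape")
    return np.abs(a - b) / np.sqrt(2.0)


def snr(signal_b0: np.ndarray, noise_image: np.ndarray,
        mask: np.ndarray) -> float | None:
    """In-mask spatial-mean ratio of signal to noise image.

    Returns None (not evaluable) when the in-mask noise mean is zero —
    the noiseless limit, where SNR is unbounded.
    """
    signal_b0 = np.asarray(signal_b0, dtype=float)
    noise_image = np.asarray(noise_image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    noise_mean = float(noise_image[mask].mean())
    if noise_mean == 0.0:
        return None
    return float(signal_b0[mask].mean() / noise_mean)
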