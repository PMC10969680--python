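"""End-to-end phantom QC pipeline.

``phantom_performance`` turns a set of repeated phantom exams into the
full performance-metric panel (bias, RC/wCV, linearity, b-value
dependence, random error, SNR); ``run_pipeline`` orchestrates
simulate -> fit -> VOI statistics -> metrics -> conformance and writes
machine- and human-readable reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .adc import FitOptions, compute_adc_map, fit_adc_twopoint
from .conformance import ConformanceReport, check_claims, \
    check_protocol_compliance
from .metrics import (MetricResult, RepeatedMeasurements, adc_bias,
                      bvalue_dependence, linearity, make_noise_image,
                      random_error, repeatability, snr)
from .phantom import (DWISeries, NoiseModel, PhantomLayout,
                      clinical_brain_params, default_layout,
                      qiba_phantom_params, simulate_repeated_exams)
from .roi import voi_statistics

__all__ = ["PhantomMetricsResult", "phantom_performance", "RunConfig",
           "run_pipeline"]

log = logging.getLogger("qdwiqc")


@dataclass
class PhantomMetricsResult:
    """Metric panel plus the per-exam VOI means behind it."""

    metrics: list[MetricResult]
    vial_means: pd.DataFrame  # rows: exam repeat, columns: vial label

    def metric(self, name: str) -> MetricResult:
        return next(m for m in self.metrics if m.name == name)


def _two_point_voi_mean(series: DWISeries, mask, b_index: int) -> float:
    """VOI-mean ADC of the (b_min, b_index) two-point voxelwise fit."""
    b = series.params.b_values
    s_lo = series.signal[..., 0]
    s_hi = series.signal[..., b_index]
    with np.errstate(divide="ignore", invalid="ignore"):
        adc = np.where(
            (s_lo > 0) & (s_hi > 0),
            np.log(np.clip(s_lo, 1e-300, None)
                   / np.clip(s_hi, 1e-300, None))
            / (b[b_index] - b[0]) * 1e6,
            np.nan)
    return voi_statistics(adc, mask, label=f"b{b[b_index]:g}").mean


def phantom_performance(
    exams: list[DWISeries],
    layout: PhantomLayout,
    fit_options: FitOptions | None = None,
) -> PhantomMetricsResult:
    """Compute the full performance-metric panel from repeated exams.

    The central (0% PVP) vial carries the bias, repeatability, b-value
    dependence, random-error and SNR metrics; linearity uses the mean
    measured ADC of every vial against its ground truth.
    """
    if not exams:
        raise ValueError("need at least one exam")
    fit_options = fit_options or FitOptions()
    masks = {v.label: layout.vial_mask(v.label) for v in layout.vials}
    central = layout.central_vial

    rows = []
    central_vois = []
    for exam in exams:
        adc_map = compute_adc_map(exam, fit_options)
        row = {}
        for label, mask in masks.items():
            stats = voi_statistics(adc_map.values, mask, label=label)
            row[label] = stats.mean
            if label == central.label:
                central_vois.append(stats)
        rows.append(row)
    vial_means = pd.DataFrame(rows)

    dc_true = central.true_adc
    mu = float(vial_means[central.label].mean())
    bias, pct_bias = adc_bias(mu, dc_true)

    metrics = [MetricResult(
        "adc_bias_pct", pct_bias, "%",
        detail={"bias": bias, "mu": mu, "dc_true": dc_true})]

    if len(exams) >= 2:
        rep = repeatability(RepeatedMeasurements(
            {central.label: list(vial_means[central.label])}))
        metrics.append(MetricResult("rc_short_term", rep.rc, "um^2/s",
                                    detail={"sigma_w": rep.sigma_w}))
        metrics.append(MetricResult("wcv_short_term_pct", rep.wcv_percent,
                                    "%"))
    else:
        metrics.append(MetricResult("rc_short_term", None, "um^2/s"))
        metrics.append(MetricResult("wcv_short_term_pct", None, "%"))

    if len(layout.vials) >= 3:
        points = [(v.true_adc, float(vial_means[v.label].mean()))
                  for v in layout.vials]
        fit = linearity(points)
        metrics.append(MetricResult(
            "linearity_slope_ci", fit.slope, "",
            detail={"ci": fit.slope_ci, "intercept": fit.intercept}))
        metrics.append(MetricResult("linearity_r_squared", fit.r_squared,
                                    ""))
    else:
        metrics.append(MetricResult("linearity_slope_ci", None, ""))
        metrics.append(MetricResult("linearity_r_squared", None, ""))

    b = exams[0].params.b_values
    nonzero = [i for i in range(1, len(b))]
    if len(nonzero) >= 2:
        per_b = {b[i]: float(np.mean([
            _two_point_voi_mean(exam, masks[central.label], i)
            for exam in exams])) for i in nonzero}
        dep = bvalue_dependence(per_b)
    else:
        dep = None
    metrics.append(MetricResult("bvalue_dependence_pct", dep, "%"))

    metrics.append(MetricResult("random_error_pct",
                                random_error(central_vois[0]), "%"))

    if len(exams) >= 2:
        noise_img = make_noise_image(exams[0].signal[..., 0],
                                     exams[1].signal[..., 0])
        snr_val = snr(exams[0].signal[..., 0], noise_img,
                      masks[central.label])
    else:
        snr_val = None
    metrics.append(MetricResult("snr_b0", snr_val, ""))

    return PhantomMetricsResult(metrics=metrics, vial_means=vial_means)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class RunConfig:
    """One end-to-end phantom QC run."""

    protocol: str = "qiba_phantom"  # qiba_phantom | clinical_brain
    n_repeats: int = 4
    seed: int = 0
    noise_kind: str = "none"
    noise_sigma: float = 0.0
    fit_method: str | None = None  # default: per protocol
    out_dir: str = "qc_out"
    layout_config: dict = field(default_factory=dict)
    protocol_overrides: dict = field(default_factory=dict)
    waivers: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**doc)

    def config_hash(self) -> str:
        """Fingerprint of the scientific configuration (output paths
        excluded)."""
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> ConformanceReport:
    """Simulate, fit, measure and check conformance; write reports.

    Deterministic for a fixed seed; every report embeds the seed and a
    hash of the configuration.
    """
    from .phantom import make_phantom_layout

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    layout = make_phantom_layout(**config.layout_config) \
        if config.layout_config else default_layout()
    if config.protocol == "qiba_phantom":
        params = qiba_phantom_params(**config.protocol_overrides)
        fit_method = config.fit_method or "loglinear"
    elif config.protocol == "clinical_brain":
        params = clinical_brain_params(**config.protocol_overrides)
        fit_method = config.fit_method or "two_point"
    else:
        raise ValueError(f"unknown protocol {config.protocol!r}")
    noise = NoiseModel(config.noise_kind, config.noise_sigma)

    log.info("simulate: protocol=%s repeats=%d noise=%s sigma=%g seed=%d",
             config.protocol, config.n_repeats, noise.kind, noise.sigma,
             config.seed)
    exams = simulate_repeated_exams(layout, params, noise,
                                    n_repeats=config.n_repeats,
                                    seed=config.seed)

    log.info("fit+metrics: method=%s", fit_method)
    result = phantom_performance(exams, layout,
                                 FitOptions(method=fit_method))
    for m in result.metrics:
        log.info("metric %s = %s %s", m.name, m.value, m.units)

    claim_report = check_claims(result.metrics)
    proto_report = check_protocol_compliance(
        params, profile=config.protocol, waivers=config.waivers)
    report = ConformanceReport(metrics=claim_report.metrics,
                               parameters=proto_report.parameters)

    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "protocol": config.protocol, "fit_method": fit_method}
    (out / "report.json").write_text(json.dumps(
        {**meta, **report.to_dict()}, indent=1, default=_json_default))
    (out / "report.txt").write_text(
        f"# seed={config.seed} config={config.config_hash()}\n"
        + report.to_text() + "\n")
    rows = [{"metric": m.name, "value": m.value, "units": m.units,
             "claim": m.claim,
             "passed": {True: "pass", False: "fail",
                        None: "not_evaluable"}[m.passed]}
            for m in report.metrics]
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    result.vial_means.to_csv(out / "vial_means.csv", index=False)
    log.info("overall pass: %s", report.overall_pass)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
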