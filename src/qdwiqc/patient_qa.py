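"""Patient-stage quality assurance.

Three computations on clinical scans acquired with a validated
protocol:

* aggregation of radiologist image-quality scorecards (seven artifact
  items on a 3-point scale: 1 unacceptable, 2 acceptable, 3 ideal);
* tissue-ROI repeatability/reproducibility (RC and wCV per scanner and
  tissue, patients as subjects);
* comparison of measured CSF ADC with the experimental ADC of free
  water at body temperature, 3037.7 um^2/s — CSF in the lateral
  ventricle is the closest in-vivo surrogate of a water standard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import RepeatabilityResult, RepeatedMeasurements, repeatability
from .phantom import PatientScanSet

__all__ = [
    "SCORECARD_ITEMS", "QualityScorecard", "TissueReference",
    "WATER_ADC_37C", "aggregate_quality", "tissue_repeatability",
    "csf_water_comparison",
]

SCORECARD_ITEMS = (
    "low_snr", "ghost_parallel", "spatial_distortion", "eddy_currents",
    "fat_suppression", "motion", "nyquist_ghost",
)

#: experimental ADC of water at 37 degrees C, um^2/s
WATER_ADC_37C = 3037.7


@dataclass(frozen=True)
class QualityScorecard:
    """Per-scan 3-point artifact scores."""

    scan_id: str
    scanner_id: str
    scores: dict[str, int]

    def __post_init__(self) -> None:
        missing = [i for i in SCORECARD_ITEMS if i not in self.scores]
        if missing:
            raise ValueError(f"scan {self.scan_id!r}: missing items "
                             f"{missing}")
        bad = {k: v for k, v in self.scores.items() if v not in (1, 2, 3)}
        if bad:
            raise ValueError(f"scan {self.scan_id!r}: scores outside "
                             f"{{1,2,3}}: {bad}")


@dataclass(frozen=True)
class TissueReference:
    tissue: str
    reference_adc: float  # um^2/s
    note: str = ""

    def __post_init__(self) -> None:
        if self.reference_adc <= 0:
            raise ValueError("reference ADC must be > 0")


CSF_WATER_REFERENCE = TissueReference(
    "csf", WATER_ADC_37C, "experimental ADC of water at 37 C")


def aggregate_quality(scorecards: list[QualityScorecard]) -> pd.DataFrame:
    """Per-scanner, per-item mean +/- sample SD with unacceptable flag.

    Returns a frame indexed by (scanner_id, item) with columns
    ``mean``, ``sd``, ``n_scans`` and ``any_unacceptable`` (True iff any
    scan scored 1 on that item).
    """
    if not scorecards:
        raise ValueError("no scorecards given")
    rows = []
    for card in scorecards:
        for item in SCORECARD_ITEMS:
            rows.append({"scanner_id": card.scanner_id, "item": item,
                         "score": card.scores[item]})
    df = pd.DataFrame(rows)
    out = df.groupby(["scanner_id", "item"], sort=False)["score"].agg(
        mean="mean",
        sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
        n_scans="count",
        any_unacceptable=lambda s: bool((s == 1).any()),
    )
    return out


def tissue_repeatability(
    scans: PatientScanSet,
    tissue: str,
    scanner_id: str | None = None,
    term: str = "long_term",
    pooled: bool = False,
) -> tuple[float, float, RepeatabilityResult | None]:
    """Tissue-ROI ADC summary and repeatability for one scanner.

    Returns ``(mean_adc, sd_adc, repeatability)`` where the mean/SD are
    across all matching scans.  ``pooled=False`` (repeatability) groups
    scans by patient and needs at least one patient with >= 2 scans;
    when none exists the third element is None (not evaluable).
    ``pooled=True`` (reproducibility) treats all scans of the scanner as
    repeated measurements of one group.
    """
    df = scans.records
    sel = df[df["tissue"] == tissue]
    if scanner_id is not None:
        sel = sel[sel["scanner_id"] == scanner_id]
    if sel.empty:
        raise ValueError(f"no scans for tissue {tissue!r}"
                         + (f" on {scanner_id!r}" if scanner_id else ""))
    values = sel["roi_mean_adc"].to_numpy(dtype=float)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    if pooled:
        groups = {"pooled": list(values)} if len(values) >= 2 else {}
    else:
        groups = {
            pid: list(g["roi_mean_adc"])
            for pid, g in sel.groupby("patient_id")
            if len(g) >= 2
        }
    rep = None
    if groups:
        rep = repeatability(RepeatedMeasurements(groups, term=term))
    return mean, sd, rep


def csf_water_comparison(
    csf_means: list[float],
    reference: TissueReference = CSF_WATER_REFERENCE,
) -> dict:
    """Absolute differences between measured CSF ADCs and the water
    reference, with their min and max."""
    if not csf_means:
        raise ValueError("csf_means is empty")
    diffs = [abs(float(m) - reference.reference_adc) for m in csf_means]
    return {
        "reference": reference.reference_adc,
        "differences": diffs,
        "min": float(np.min(diffs)),
        "max": float(np.max(diffs)),
    }
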