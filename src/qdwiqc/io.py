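"""Standard-format I/O: NIfTI exam volumes with JSON sidecars, ROI and
scorecard tables.

A DWI exam is stored as a 4-D NIfTI-1 file (slice, row, col, b) next to
a JSON sidecar ``<stem>.json`` holding the acquisition metadata; the
sidecar's ``b_values`` length must match the 4th axis.  ADC maps are 3-D
NIfTI with a sidecar recording the fit method and b-values used.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .adc import ADCMap
from .patient_qa import SCORECARD_ITEMS, QualityScorecard
from .phantom import AcquisitionParams, DWISeries
from .roi import ROISpec

__all__ = [
    "FormatError", "write_dwi", "read_dwi", "write_adc_map",
    "read_adc_map", "read_roi_specs", "read_scorecards",
]


class FormatError(ValueError):
    """A file does not match the expected on-disk layout."""


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_dwi(series: DWISeries, path) -> Path:
    """Write a DWI exam as 4-D NIfTI plus JSON sidecar; returns the
    image path."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(series.signal, dtype=np.float64),
                          affine=np.eye(4))
    nib.save(img, str(path))
    sidecar = {
        **series.params.to_dict(),
        "exam_id": series.exam_id,
        "repeat_index": series.repeat_index,
        "session_date": series.session_date,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_dwi(path) -> DWISeries:
    """Read a DWI exam written by :func:`write_dwi`."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar_file.name}")
    meta = json.loads(sidecar_file.read_text())
    data = np.asanyarray(nib.load(str(path)).dataobj)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4-D DWI volume, got "
                          f"{data.ndim}-D")
    exam_id = meta.pop("exam_id", path.stem)
    repeat_index = int(meta.pop("repeat_index", 0))
    session_date = int(meta.pop("session_date", 0))
    params = AcquisitionParams.from_dict(meta)
    if data.shape[-1] != params.n_bvalues:
        raise FormatError(
            f"{path}: volume has {data.shape[-1]} b-volumes but sidecar "
            f"lists {params.n_bvalues} b-values")
    return DWISeries(data.astype(float), params, exam_id=exam_id,
                     repeat_index=repeat_index, session_date=session_date)


def write_adc_map(adc: ADCMap, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(adc.values, dtype=np.float64),
                          affine=np.eye(4))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({
        "method": adc.method,
        "b_values": list(adc.b_values),
        "units": "um^2/s",
        "exam_id": adc.exam_id,
    }, indent=1))
    return path


def read_adc_map(path) -> ADCMap:
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"{path}: missing JSON sidecar")
    meta = json.loads(sidecar_file.read_text())
    values = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    return ADCMap(values, np.full_like(values, np.nan), meta["method"],
                  tuple(meta["b_values"]), exam_id=meta.get("exam_id", ""))


def read_roi_specs(path) -> list[ROISpec]:
    """ROI definitions from YAML (list of mappings) or CSV with columns
    label, slice, row, col, diameter_mm[, tissue]."""
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        entries = yaml.safe_load(path.read_text())
    else:
        entries = pd.read_csv(path).to_dict("records")
    specs = []
    for e in entries:
        try:
            specs.append(ROISpec(
                label=str(e["label"]),
                slice_index=int(e["slice"]),
                center=(float(e["row"]), float(e["col"])),
                diameter_mm=float(e["diameter_mm"]),
                tissue=str(e.get("tissue", "") or ""),
            ))
        except KeyError as exc:
            raise FormatError(f"{path}: ROI entry missing field {exc}")
    return specs


def read_scorecards(path) -> list[QualityScorecard]:
    """Image-quality scorecards from CSV: scan_id, scanner_id plus one
    column per artifact item."""
    df = pd.read_csv(path)
    missing = [c for c in ("scan_id", "scanner_id", *SCORECARD_ITEMS)
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return [
        QualityScorecard(
            scan_id=str(row["scan_id"]),
            scanner_id=str(row["scanner_id"]),
            scores={item: int(row[item]) for item in SCORECARD_ITEMS},
        )
        for _, row in df.iterrows()
    ]
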