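"""Synthetic diffusion phantom and patient-cohort generators.

The phantom emulates a multi-vial diffusion phantom: cylindrical vials of
polyvinylpyrrolidone (PVP) solutions embedded in an ice-water bath, each
vial with a known ground-truth apparent diffusion coefficient (ADC).  The
0%-PVP (pure water) central vial carries the reference value
``DC_true = 1100`` |um2s| (water at the phantom's controlled temperature).

Signal follows the mono-exponential diffusion model

    S(b) = S0 * exp(-b * ADC)

with b in s/mm^2 and ADC stored in um^2/s throughout the package
(1e-3 mm^2/s = 1e3 um^2/s); the exponent therefore uses ``ADC * 1e-6``.

Magnitude-MRI noise is Rician: two independent Gaussian channels of
standard deviation sigma are added in quadrature,
``sqrt((S + n1)^2 + n2^2)``.  NEX (number of excitations) averages that
many independent magnitude images, as a single-coil scanner would.

.. |um2s| replace:: um^2/s
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "VialSpec",
    "PhantomLayout",
    "AcquisitionParams",
    "NoiseModel",
    "DWISeries",
    "PatientScanSet",
    "make_phantom_layout",
    "default_layout",
    "small_layout",
    "qiba_phantom_params",
    "clinical_brain_params",
    "simulate_dwi_exam",
    "simulate_repeated_exams",
    "simulate_patient_cohort",
    "sigma_for_snr",
    "WATER_ADC_0PVP",
]

#: ground-truth ADC of the 0% PVP (pure water) vial, um^2/s
WATER_ADC_0PVP = 1100.0


class GeometryError(ValueError):
    """Vial layout violates the grid or overlap constraints."""


@dataclass(frozen=True)
class VialSpec:
    """One phantom vial: a cylinder through all slices of the grid."""

    label: str
    center: tuple[float, float]  # (row, col) in voxel units
    radius_mm: float
    true_adc: float  # um^2/s
    s0: float = 1000.0  # signal at b=0, arbitrary units
    pvp_concentration: float | None = None  # % w/w, informational

    def __post_init__(self) -> None:
        if self.true_adc <= 0:
            raise ValueError(f"vial {self.label!r}: true_adc must be > 0")
        if self.radius_mm <= 0:
            raise GeometryError(f"vial {self.label!r}: radius must be > 0")
        if self.s0 <= 0:
            raise ValueError(f"vial {self.label!r}: s0 must be > 0")


@dataclass(frozen=True)
class PhantomLayout:
    """Geometry and ground truth of the synthetic phantom."""

    vials: tuple[VialSpec, ...]
    grid_shape: tuple[int, int, int]  # (n_slices, n_rows, n_cols)
    voxel_size_mm: float
    central_label: str = "central"
    background: float = 0.0

    def __post_init__(self) -> None:
        if not self.vials:
            raise GeometryError("layout needs at least one vial")
        labels = [v.label for v in self.vials]
        if len(set(labels)) != len(labels):
            raise GeometryError("vial labels must be unique")
        if self.central_label not in labels:
            raise GeometryError(
                f"central vial {self.central_label!r} not in layout"
            )
        _, n_rows, n_cols = self.grid_shape
        for v in self.vials:
            r_vox = v.radius_mm / self.voxel_size_mm
            row, col = v.center
            if (row - r_vox < -0.5 or row + r_vox > n_rows - 0.5
                    or col - r_vox < -0.5 or col + r_vox > n_cols - 0.5):
                raise GeometryError(f"vial {v.label!r} extends outside grid")
        for i, a in enumerate(self.vials):
            for b in self.vials[i + 1:]:
                dist = math.hypot(a.center[0] - b.center[0],
                                  a.center[1] - b.center[1])
                if dist * self.voxel_size_mm < a.radius_mm + b.radius_mm:
                    raise GeometryError(
                        f"vials {a.label!r} and {b.label!r} overlap"
                    )

    @property
    def central_vial(self) -> VialSpec:
        return next(v for v in self.vials if v.label == self.central_label)

    def vial_mask(self, label: str) -> np.ndarray:
        """Boolean 3-D footprint of a vial (cylinder through all slices).

        A voxel belongs to the vial iff its center lies strictly inside
        the vial circle, the same rule the simulator uses, so the mask is
        free of partial-volume voxels.
        """
        vial = next((v for v in self.vials if v.label == label), None)
        if vial is None:
            raise KeyError(f"no vial labelled {label!r}")
        n_slices, n_rows, n_cols = self.grid_shape
        rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols),
                             indexing="ij")
        r_vox = vial.radius_mm / self.voxel_size_mm
        inside = ((rr - vial.center[0]) ** 2
                  + (cc - vial.center[1]) ** 2) < r_vox ** 2
        return np.broadcast_to(inside, (n_slices, n_rows, n_cols)).copy()


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata for one DWI exam."""

    b_values: tuple[float, ...]  # s/mm^2, strictly increasing
    tr_ms: float = 8000.0
    te_ms: float = 55.0
    field_strength_T: float = 3.0
    matrix: tuple[int, int] = (128, 128)  # frequency x phase
    fov_mm: float = 220.0
    slice_thickness_mm: float = 4.0
    gap_mm: float = 1.0
    nex: int = 2
    n_slices: int = 25
    parallel_factor: float = 2.0
    half_scan_factor: float = 0.8
    fat_suppression: str = "STIR"
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.b_values) == 0:
            raise ValueError("b_values must be nonempty")
        b = np.asarray(self.b_values, dtype=float)
        if np.any(b < 0):
            raise ValueError("b_values must be nonnegative")
        if np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if self.nex < 1:
            raise ValueError("nex must be >= 1")

    @property
    def n_bvalues(self) -> int:
        return len(self.b_values)

    def to_dict(self) -> dict:
        return {
            "b_values": list(self.b_values),
            "tr_ms": self.tr_ms,
            "te_ms": self.te_ms,
            "field_strength_T": self.field_strength_T,
            "matrix": list(self.matrix),
            "fov_mm": self.fov_mm,
            "slice_thickness_mm": self.slice_thickness_mm,
            "gap_mm": self.gap_mm,
            "nex": self.nex,
            "n_slices": self.n_slices,
            "parallel_factor": self.parallel_factor,
            "half_scan_factor": self.half_scan_factor,
            "fat_suppression": self.fat_suppression,
            **({"extras": self.extras} if self.extras else {}),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionParams":
        d = dict(d)
        d["b_values"] = tuple(float(b) for b in d["b_values"])
        if "matrix" in d:
            d["matrix"] = tuple(int(m) for m in d["matrix"])
        known = {f for f in cls.__dataclass_fields__}  # noqa: C416
        extras = d.pop("extras", {})
        extras.update({k: d.pop(k) for k in list(d) if k not in known})
        return cls(extras=extras, **d)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description for the simulator.

    ``rician`` adds two independent Gaussian channels and takes the
    magnitude; ``gaussian`` adds a single channel (useful for analytic
    checks); ``none`` is the noiseless limit.
    """

    kind: str = "none"  # rician | gaussian | none
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("rician", "gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class DWISeries:
    """One DWI exam: 4-D signal (slice, row, col, b) plus metadata."""

    signal: np.ndarray
    params: AcquisitionParams
    exam_id: str = "exam"
    repeat_index: int = 0
    session_date: int = 0  # ordinal day

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (slice, row, col, b)")
        if self.signal.shape[-1] != self.params.n_bvalues:
            raise ValueError(
                f"signal has {self.signal.shape[-1]} b-volumes but params "
                f"list {self.params.n_bvalues} b-values"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be nonnegative")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[:3]

    def b_volume(self, b: float) -> np.ndarray:
        """Return the 3-D volume acquired at b-value ``b``."""
        idx = list(self.params.b_values).index(b)
        return self.signal[..., idx]


@dataclass
class PatientScanSet:
    """Longitudinal per-patient ROI ADC observations (one row per scan)."""

    records: "pd.DataFrame"  # noqa: F821 - imported lazily

    COLUMNS = ("patient_id", "scanner_id", "session_date", "tissue",
               "roi_mean_adc", "roi_sd", "n_voxels")

    def __post_init__(self) -> None:
        import pandas as pd

        df = pd.DataFrame(self.records, columns=list(self.COLUMNS))
        if (df["roi_mean_adc"] <= 0).any():
            raise ValueError("roi_mean_adc must be > 0")
        key = ["patient_id", "scanner_id", "session_date", "tissue"]
        if df.duplicated(subset=key).any():
            raise ValueError("duplicate (patient, scanner, date, tissue) row")
        self.records = df

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PatientScanSet":
        import pandas as pd

        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# layout construction

#: default ground-truth ADC ladder (um^2/s) for non-central vials;
#: monotone decreasing from the water value, mimicking increasing PVP
#: concentration.  Only the 0%-PVP value is reference-anchored.
DEFAULT_ADC_LADDER = (1000.0, 900.0, 800.0, 700.0, 600.0, 500.0,
                      450.0, 400.0, 300.0, 250.0, 180.0, 130.0)


def make_phantom_layout(
    n_vials: int = 13,
    grid_shape: tuple[int, int, int] = (3, 128, 128),
    voxel_size_mm: float = 1.72,
    vial_radius_mm: float = 10.0,
    central_adc: float = WATER_ADC_0PVP,
    adc_ladder: tuple[float, ...] | None = None,
    s0: float = 1000.0,
    ring_radii_mm: tuple[float, ...] | None = None,
) -> PhantomLayout:
    """Build a phantom layout: one central water vial plus rings of vials.

    Parameters
    ----------
    n_vials:
        Total vial count (central vial included).
    central_adc:
        Ground-truth ADC of the central 0%-PVP vial (um^2/s).
    adc_ladder:
        True ADCs of the remaining vials; defaults to a monotone
        decreasing ladder below the water value.
    ring_radii_mm:
        Radii of the concentric rings the outer vials sit on; chosen
        automatically from the grid size when omitted.
    """
    if n_vials < 1:
        raise GeometryError("need at least one vial")
    n_slices, n_rows, n_cols = grid_shape
    center = ((n_rows - 1) / 2.0, (n_cols - 1) / 2.0)
    vials = [VialSpec("central", center, vial_radius_mm, central_adc,
                      s0=s0, pvp_concentration=0.0)]
    n_outer = n_vials - 1
    if n_outer:
        ladder = tuple(adc_ladder) if adc_ladder is not None \
            else DEFAULT_ADC_LADDER
        if len(ladder) < n_outer:
            raise ValueError(
                f"adc ladder has {len(ladder)} values for {n_outer} vials"
            )
        half_extent = (min(n_rows, n_cols) - 1) / 2.0 * voxel_size_mm
        if ring_radii_mm is None:
            if n_outer <= 6:
                ring_radii_mm = (half_extent - vial_radius_mm - 2.0,)
            else:
                ring_radii_mm = (
                    (half_extent - vial_radius_mm) * 0.52,
                    half_extent - vial_radius_mm - 2.0,
                )
        per_ring = int(np.ceil(n_outer / len(ring_radii_mm)))
        k = 0
        for i_ring, ring_r in enumerate(ring_radii_mm):
            n_here = min(per_ring, n_outer - k)
            offset = (math.pi / n_here) * (i_ring % 2) if n_here else 0.0
            for j in range(n_here):
                theta = 2 * math.pi * j / n_here + offset
                row = center[0] + (ring_r / voxel_size_mm) * math.sin(theta)
                col = center[1] + (ring_r / voxel_size_mm) * math.cos(theta)
                vials.append(VialSpec(f"vial{k + 1:02d}", (row, col),
                                      vial_radius_mm, ladder[k], s0=s0))
                k += 1
    return PhantomLayout(tuple(vials), grid_shape, voxel_size_mm)


def default_layout() -> PhantomLayout:
    """13-vial demo layout on a 128x128 grid (three slices)."""
    return make_phantom_layout()


def small_layout() -> PhantomLayout:
    """Compact 5-vial layout for Monte-Carlo studies (64x64, 5 slices)."""
    return make_phantom_layout(n_vials=5, grid_shape=(5, 64, 64),
                               vial_radius_mm=10.0,
                               adc_ladder=(900.0, 600.0, 400.0, 250.0),
                               ring_radii_mm=(32.0,))


def qiba_phantom_params(**overrides) -> AcquisitionParams:
    """Acquisition parameters of the phantom validation protocol."""
    defaults = dict(
        b_values=(0.0, 500.0, 1000.0, 1500.0, 2000.0),
        tr_ms=8000.0, te_ms=55.0, matrix=(128, 128), fov_mm=220.0,
        slice_thickness_mm=4.0, gap_mm=1.0, nex=2, n_slices=25,
        parallel_factor=2.0, half_scan_factor=0.8,
    )
    defaults.update(overrides)
    return AcquisitionParams(**defaults)


def clinical_brain_params(**overrides) -> AcquisitionParams:
    """Acquisition parameters of the two-b-value clinical brain protocol."""
    defaults = dict(
        b_values=(0.0, 1000.0),
        tr_ms=3000.0, te_ms=55.0, matrix=(128, 128), fov_mm=240.0,
        slice_thickness_mm=5.0, gap_mm=2.0, nex=1, n_slices=25,
        parallel_factor=2.0, half_scan_factor=0.811,
    )
    defaults.update(overrides)
    return AcquisitionParams(**defaults)


# ---------------------------------------------------------------------------
# forward simulation

def _noiseless_volume(layout: PhantomLayout, b_values: np.ndarray
                      ) -> np.ndarray:
    n_slices, n_rows, n_cols = layout.grid_shape
    out = np.full((n_slices, n_rows, n_cols, len(b_values)),
                  layout.background, dtype=float)
    for vial in layout.vials:
        mask = layout.vial_mask(vial.label)
        # ADC um^2/s * 1e-6 -> mm^2/s so that b*ADC is dimensionless
        decay = vial.s0 * np.exp(-b_values * vial.true_adc * 1e-6)
        out[mask, :] = decay
    return out


def _apply_noise(clean: np.ndarray, noise: NoiseModel, nex: int,
                 rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none" or noise.sigma == 0.0:
        return clean.copy()
    acc = np.zeros_like(clean)
    for _ in range(nex):
        if noise.kind == "rician":
            n1 = rng.normal(0.0, noise.sigma, size=clean.shape)
            n2 = rng.normal(0.0, noise.sigma, size=clean.shape)
            acc += np.sqrt((clean + n1) ** 2 + n2 ** 2)
        else:  # gaussian
            acc += np.clip(
                clean + rng.normal(0.0, noise.sigma, size=clean.shape),
                0.0, None)
    return acc / nex


def simulate_dwi_exam(
    layout: PhantomLayout,
    params: AcquisitionParams,
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
    exam_id: str = "exam",
    repeat_index: int = 0,
    session_date: int = 0,
) -> DWISeries:
    """Simulate one phantom DWI exam under the mono-exponential model.

    With ``noise.kind == "none"`` every vial voxel equals
    ``s0 * exp(-b * true_adc * 1e-6)`` exactly.  Rician noise reconstructs
    the magnitude from two Gaussian channels; ``params.nex`` magnitude
    images are averaged.  Deterministic for a fixed seed.
    """
    b = np.asarray(params.b_values, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    clean = _noiseless_volume(layout, b)
    signal = _apply_noise(clean, noise, params.nex, rng)
    return DWISeries(signal, params, exam_id=exam_id,
                     repeat_index=repeat_index, session_date=session_date)


def simulate_repeated_exams(
    layout: PhantomLayout,
    params: AcquisitionParams,
    noise: NoiseModel = NoiseModel(),
    n_repeats: int = 4,
    inter_exam_cv: float = 0.0,
    seed: int = 0,
    session_date: int = 0,
    exam_id: str = "exam",
) -> list[DWISeries]:
    """Simulate a repeated-exam session (intra-day test-retest design).

    ``inter_exam_cv`` is a fractional multiplicative drift of s0 between
    repeats (scanner gain instability); with it at 0 and no noise all
    repeats are identical.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2 for a repeatability design")
    if inter_exam_cv < 0:
        raise ValueError("inter_exam_cv must be >= 0")
    rng = np.random.default_rng(seed)
    series = []
    for i in range(n_repeats):
        lay = layout
        if inter_exam_cv > 0:
            gain = 1.0 + rng.normal(0.0, inter_exam_cv)
            gain = max(gain, 1e-6)
            lay = replace(layout, vials=tuple(
                replace(v, s0=v.s0 * gain) for v in layout.vials))
        series.append(simulate_dwi_exam(
            lay, params, noise, seed=rng, exam_id=f"{exam_id}-r{i}",
            repeat_index=i, session_date=session_date))
    return series


def sigma_for_snr(s0: float, snr: float, nex: int = 1) -> float:
    """Per-channel Gaussian sigma giving a target difference-method SNR.

    The b=0 SNR measured as mean(signal)/mean(|rep1-rep2|/sqrt(2)) is
    approximately ``s0 * sqrt(pi/2) / sigma_eff`` with
    ``sigma_eff = sigma / sqrt(nex)`` in the high-SNR regime.
    """
    if snr <= 0:
        raise ValueError("snr must be > 0")
    return s0 * math.sqrt(math.pi / 2.0) * math.sqrt(nex) / snr


# ---------------------------------------------------------------------------
# patient cohort

def simulate_patient_cohort(
    n_patients: int = 14,
    scans_per_patient: int = 2,
    tissue_means: dict[str, float] | None = None,
    within_subject_cv: float = 0.02,
    between_subject_cv: float = 0.05,
    seed: int = 0,
    scanner_id: str = "scanner1",
    n_voxels: dict[str, int] | None = None,
    days_between_scans: int = 90,
) -> PatientScanSet:
    """Simulate longitudinal tissue-ROI ADC observations.

    Each patient draws a true tissue mean with the between-subject CV
    around the population mean; each scan observes
    ``patient_mean * (1 + eps)`` with ``eps ~ N(0, within_subject_cv^2)``.
    Defaults mirror a brain-infarct follow-up cohort: white matter around
    800 um^2/s and CSF around 3000 um^2/s with ~2% within-subject CV.
    """
    if within_subject_cv < 0 or between_subject_cv < 0:
        raise ValueError("CVs must be >= 0")
    if scans_per_patient < 1:
        raise ValueError("scans_per_patient must be >= 1")
    if tissue_means is None:
        tissue_means = {"white_matter": 800.0, "csf": 3000.0}
    for tissue, mean in tissue_means.items():
        if mean <= 0:
            raise ValueError(f"tissue mean for {tissue!r} must be > 0")
    if n_voxels is None:
        n_voxels = {"white_matter": 98, "csf": 24}
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1:03d}"
        for tissue, mean in tissue_means.items():
            patient_mean = mean * max(
                1.0 + rng.normal(0.0, between_subject_cv), 1e-6)
            for s in range(scans_per_patient):
                obs = patient_mean * max(
                    1.0 + rng.normal(0.0, within_subject_cv), 1e-6)
                rows.append({
                    "patient_id": pid,
                    "scanner_id": scanner_id,
                    "session_date": s * days_between_scans,
                    "tissue": tissue,
                    "roi_mean_adc": obs,
                    "roi_sd": obs * 0.05,
                    "n_voxels": n_voxels.get(tissue, 50),
                })
    import pandas as pd

    return PatientScanSet(pd.DataFrame(rows))
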