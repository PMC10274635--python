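"""Synthetic ground-truth data: tube phantoms and simulated cohorts.

Two generators give every downstream stage a known answer:

* :func:`generate_tube_phantom` renders dark capsule-shaped tubes (the
  T1w appearance of perivascular spaces) inside two disjoint ROI blocks
  standing in for centrum semiovale ("CSO-like", label 1) and basal
  ganglia ("BG-like", label 2), on a brighter uniform tissue background.
  The truth mask is exactly the set of voxels whose center lies within
  the tube radius of a capsule centerline, so a brute-force distance
  count reproduces it.

* :func:`simulate_cohort` draws per-subject biomarkers and covariates,
  forms a log-linear predictor with known coefficients under the same
  centering/scaling convention the fitter applies, and samples PVS volume
  fractions from a Gamma distribution with that mean.

Both are pure functions of their spec (including the seed).
:func:`add_rician_noise` applies the magnitude-MRI noise model
``M = sqrt((A + g1*sigma)^2 + (g2*sigma)^2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import design
from .volume import Volume3D

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "COHORT_COLUMNS",
    "generate_tube_phantom",
    "add_rician_noise",
    "simulate_cohort",
]


# ---------------------------------------------------------------------------
# Phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of a tube phantom.

    ``target_vf`` overrides ``n_tubes``: the number of tubes per ROI is
    chosen so the expected tube volume fraction matches it.  Intensities
    are arbitrary units with ``tube_intensity < tissue_intensity`` for a
    T1w-like dark-PVS contrast.  ``rician_sigma`` is applied by
    :func:`generate_tube_phantom` only if nonzero; usually noise is added
    separately so the noise-free volume stays available.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_tubes: int = 12
    radius_range: tuple[float, float] = (1.0, 2.0)
    length_range: tuple[float, float] = (10.0, 22.0)
    tissue_intensity: float = 100.0
    tube_intensity: float = 30.0
    roi_margin: int = 3
    roi_gap: int = 2
    rician_sigma: float = 0.0
    partial_volume: bool = False
    curvature: float = 0.25
    #: scalar target fraction for both ROIs, or per-label {1: vf, 2: vf}
    target_vf: float | dict[int, float] | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 16 for s in self.shape):
            raise ValueError("shape must be 3 axes of at least 16 voxels")
        if self.radius_range[0] <= 0 or self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must satisfy 0 < min <= max")
        if self.tube_intensity == self.tissue_intensity:
            raise ValueError("tube_intensity must differ from tissue_intensity")
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be >= 0")
        if self.n_tubes < 0:
            raise ValueError("n_tubes must be >= 0")
        if self.target_vf is not None:
            targets = (self.target_vf.values() if isinstance(self.target_vf, dict)
                       else [self.target_vf])
            if any(not (0 <= t < 1) for t in targets):
                raise ValueError("target_vf must lie in [0, 1)")


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom volume."""

    pvs_mask: np.ndarray                 # bool, tube voxels
    roi_labels: np.ndarray               # int, 0 background / 1 CSO-like / 2 BG-like
    true_vf_per_roi: dict[int, float]    # label -> tube voxels in ROI / ROI voxels
    #: capsule definitions (polyline vertices, radius) for independent checks
    tubes: list[tuple[np.ndarray, float]] = field(default_factory=list)

    def roi_mask(self, label: int) -> np.ndarray:
        return self.roi_labels == label


def _roi_boxes(spec: PhantomSpec) -> dict[int, tuple[slice, slice, slice]]:
    """Two disjoint axis-aligned ROI blocks split along axis 0."""
    nx, ny, nz = spec.shape
    m, g = spec.roi_margin, spec.roi_gap
    half = nx // 2
    boxes = {
        1: (slice(m, half - g), slice(m, ny - m), slice(m, nz - m)),
        2: (slice(half + g, nx - m), slice(m, ny - m), slice(m, nz - m)),
    }
    for label, box in boxes.items():
        if any(s.stop - s.start < 6 for s in box):
            raise ValueError(f"ROI {label} too small for phantom shape {spec.shape}")
    return boxes


def _segment_distance(points: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    """Distance from each point to the segment p0-p1 (voxel units)."""
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        return np.linalg.norm(points - p0, axis=-1)
    t = np.clip(((points - p0) @ d) / denom, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(points - proj, axis=-1)


def _render_capsule(dist_min: np.ndarray, polyline: np.ndarray, radius: float) -> None:
    """Update the running minimum centerline distance for one tube."""
    shape = dist_min.shape
    pad = radius + 1.5
    lo = np.maximum(np.floor(polyline.min(axis=0) - pad).astype(int), 0)
    hi = np.minimum(np.ceil(polyline.max(axis=0) + pad).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return
    grid = np.stack(
        np.meshgrid(*[np.arange(lo[i], hi[i]) for i in range(3)], indexing="ij"), axis=-1
    ).astype(float)
    dmin = np.full(grid.shape[:-1], np.inf)
    for a, b in zip(polyline[:-1], polyline[1:]):
        np.minimum(dmin, _segment_distance(grid, a, b), out=dmin)
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    np.minimum(dist_min[sl], dmin, out=dist_min[sl])


def _sample_tube(rng: np.random.Generator, box: tuple[slice, slice, slice],
                 spec: PhantomSpec) -> tuple[np.ndarray, float]:
    """Draw one capsule (polyline + radius) fully inside the ROI box."""
    lo = np.array([s.start for s in box], dtype=float)
    hi = np.array([s.stop - 1 for s in box], dtype=float)
    length_min, length_max = spec.length_range
    for attempt in range(600):
        radius = rng.uniform(*spec.radius_range)
        # shrink the admissible region so the whole capsule fits
        slo, shi = lo + radius + 0.5, hi - radius - 0.5
        if np.any(shi <= slo):
            raise ValueError("infeasible phantom spec: tube radius exceeds ROI size")
        length = rng.uniform(length_min, max(length_min, length_max * 0.97 ** attempt))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        center = rng.uniform(slo, shi)
        p0 = center - 0.5 * length * direction
        p1 = center + 0.5 * length * direction
        # gentle curvature: bow the midpoint sideways
        perp = np.cross(direction, rng.normal(size=3))
        nrm = np.linalg.norm(perp)
        offset = (perp / nrm) * rng.uniform(0, spec.curvature * length / 4) if nrm > 0 else 0.0
        pm = center + offset
        pts = np.array([p0, pm, p1])
        if np.all(pts >= slo) and np.all(pts <= shi):
            return pts, radius
    raise ValueError("infeasible phantom spec: could not place a tube inside the ROI")


def _tubes_per_roi(spec: PhantomSpec) -> dict[int, int]:
    n = spec.n_tubes
    return {1: (n + 1) // 2, 2: n // 2}


def generate_tube_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Render a tube phantom and its exact ground truth.

    A voxel belongs to a tube iff its center lies within the tube radius
    of the capsule centerline.  Deterministic for a fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    boxes = _roi_boxes(spec)

    roi_labels = np.zeros(spec.shape, dtype=np.int16)
    for label, box in boxes.items():
        roi_labels[box] = label

    # minimum (distance-to-centerline - radius) over all tubes; <= 0 means inside
    signed = np.full(spec.shape, np.inf)

    tubes: list[tuple[np.ndarray, float]] = []

    def add_tube(label: int) -> None:
        polyline, radius = _sample_tube(rng, boxes[label], spec)
        tubes.append((polyline, radius))
        # track distance minus radius so tubes of different radii compose
        dist = np.full(spec.shape, np.inf)
        _render_capsule(dist, polyline, radius)
        np.minimum(signed, dist - radius, out=signed)

    if spec.target_vf is None:
        counts = _tubes_per_roi(spec)
        for label in sorted(boxes):
            for _ in range(counts[label]):
                add_tube(label)
    else:
        # add tubes until the rasterized voxel count reaches the target,
        # so the achieved fraction overshoots by at most one tube
        for label in sorted(boxes):
            target = (spec.target_vf.get(label, 0.0)
                      if isinstance(spec.target_vf, dict) else spec.target_vf)
            roi_vox = int(np.prod([s.stop - s.start for s in boxes[label]]))
            target_count = round(target * roi_vox)
            for _ in range(max(4 * target_count, 64)):
                inside = np.count_nonzero((signed[boxes[label]] <= 0.0))
                if inside >= target_count:
                    break
                add_tube(label)
            else:
                raise ValueError("infeasible phantom spec: target_vf not reachable")

    mask = signed <= 0.0
    data = np.full(spec.shape, spec.tissue_intensity, dtype=np.float64)
    if spec.partial_volume:
        # linear ramp within 0.5 voxel of the capsule surface
        frac = np.clip(0.5 - signed, 0.0, 1.0)
        data += (spec.tube_intensity - spec.tissue_intensity) * frac
    else:
        data[mask] = spec.tube_intensity

    vf = {}
    for label in sorted(boxes):
        roi = roi_labels == label
        vf[label] = float(np.count_nonzero(mask & roi) / np.count_nonzero(roi))

    vol = Volume3D(data, spec.voxel_dims)
    if spec.rician_sigma > 0:
        vol = add_rician_noise(vol, spec.rician_sigma, seed=int(rng.integers(2**31)))
    return vol, PhantomTruth(mask, roi_labels, vf, tubes)


def add_rician_noise(vol: Volume3D, sigma: float, seed: int) -> Volume3D:
    """Rician-corrupt a volume: ``M = sqrt((A + g1*s)^2 + (g2*s)^2)``.

    ``g1, g2`` are independent standard normal fields.  ``sigma=0``
    returns the input unchanged (exact copy).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return vol.like(vol.data.copy())
    rng = np.random.default_rng(seed)
    g1 = rng.standard_normal(vol.shape)
    g2 = rng.standard_normal(vol.shape)
    noisy = np.sqrt((vol.data + g1 * sigma) ** 2 + (g2 * sigma) ** 2)
    return vol.like(noisy)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Fixed column order of simulated cohort CSV files.
COHORT_COLUMNS = [
    "subject_id",
    "pvsvf_cso",
    "pvsvf_bg",
    *design.BIOMARKERS,
    "age",
    "sex",
    "bmi",
    "hippocampal_volume",
    "medication_history",
    "medication_current",
    "diagnosis",
    "apoe4_copies",
]


def _default_coefficients() -> dict[str, dict[str, float]]:
    """Generating coefficients (log scale, per-SD predictors).

    Magnitudes mirror the published exponentiated estimates for the
    centrum-semiovale cortisol x TNF-a interaction model and the basal
    ganglia TRAIL / cortisol x CRP models: intercepts exp(b0) of 0.02
    (CSO) and 0.04 (BG), a negative CSO interaction around exp(b)=0.93,
    strong positive age and BMI effects.
    """
    return {
        "pvsvf_cso": {
            "intercept": math.log(0.02),
            "cortisol": math.log(1.01),
            "tnf_a": math.log(0.96),
            "cortisol:tnf_a": math.log(0.93),
            "sex_male": math.log(1.06),
            "age": math.log(1.24),
            "bmi_z": math.log(1.07),
            "hippocampal_volume": math.log(1.04),
        },
        "pvsvf_bg": {
            "intercept": math.log(0.04),
            "cortisol": math.log(0.99),
            "crp": math.log(1.02),
            "cortisol:crp": math.log(0.98),
            "trail": math.log(1.02),
            "sex_male": math.log(1.03),
            "age": math.log(1.06),
            "bmi_z": math.log(1.05),
            "hippocampal_volume": math.log(1.02),
        },
    }


def _default_biomarker_distributions() -> dict[str, tuple[float, float]]:
    # (median ng/mL, log-scale sigma); skewed log-normal marginals.
    # Locations are plausible plasma levels, not calibrated to any cohort.
    return {
        "cortisol": (100.0, 0.35),
        "ace": (150.0, 0.40),
        "tnf_a": (5.0, 0.50),
        "tnfr2": (4.0, 0.30),
        "trail": (30.0, 0.40),
        "crp": (2000.0, 0.90),
        "il6r": (30000.0, 0.25),
        "mmp2": (600.0, 0.30),
        "mmp9": (300.0, 0.50),
    }


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort.

    ``coefficients`` maps each outcome to term->beta on the log scale;
    terms are resolved against :func:`pvskit.design.prepare_columns`
    output with ``standardize`` as given, so with the default
    ``standardize=True`` a beta is the log mean-ratio per SD of the
    predictor.  ``gamma_shape`` is the Gamma shape k (mean mu, variance
    mu^2/k); the default 2.5 reproduces standard errors near 0.03 for
    per-SD coefficients at n around 460.
    """

    n_subjects: int = 465
    coefficients: Mapping[str, Mapping[str, float]] = field(default_factory=_default_coefficients)
    gamma_shape: float = 2.5
    standardize: bool = True
    biomarker_distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_biomarker_distributions
    )
    age_mean: float = 74.85
    age_sd: float = 7.09
    age_range: tuple[float, float] = (55.0, 90.0)
    p_male: float = 0.617
    bmi_mean: float = 26.4
    bmi_sd: float = 3.9
    hippocampus_mean: float = 6500.0
    hippocampus_sd: float = 900.0
    diagnosis_probs: Mapping[str, float] = field(
        default_factory=lambda: {"CN": 48 / 465, "MCI": 325 / 465, "AD": 92 / 465}
    )
    apoe4_probs: tuple[float, float, float] = (222 / 465, 181 / 465, 62 / 465)
    medication_history_probs: tuple[float, float, float, float] = (
        408 / 477, 33 / 477, 21 / 477, 15 / 477
    )
    medication_current_probs: tuple[float, float, float] = (0.877, 0.050, 0.073)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        for name, probs in [
            ("diagnosis_probs", list(self.diagnosis_probs.values())),
            ("apoe4_probs", list(self.apoe4_probs)),
            ("medication_history_probs", list(self.medication_history_probs)),
            ("medication_current_probs", list(self.medication_current_probs)),
        ]:
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be non-negative and sum to 1")


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table with Gamma/log-link outcome structure.

    Covariates and biomarkers are drawn from the spec's distributions;
    each outcome's mean is ``exp(linear predictor)`` with the linear
    predictor built from prepared (centered/scaled) columns, and the
    observed value is Gamma(shape k, mean mu).  Deterministic for a
    fixed seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects

    df = pd.DataFrame({"subject_id": [f"S{i:04d}" for i in range(1, n + 1)]})
    for marker, (median, sig) in spec.biomarker_distributions.items():
        df[marker] = np.exp(rng.normal(math.log(median), sig, size=n))
    df["age"] = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), *spec.age_range)
    df["sex"] = np.where(rng.random(n) < spec.p_male, "M", "F")
    df["bmi"] = rng.normal(spec.bmi_mean, spec.bmi_sd, size=n)
    df["hippocampal_volume"] = rng.normal(spec.hippocampus_mean, spec.hippocampus_sd, size=n)
    dx_levels = list(spec.diagnosis_probs.keys())
    df["diagnosis"] = rng.choice(dx_levels, size=n, p=list(spec.diagnosis_probs.values()))
    df["apoe4_copies"] = rng.choice([0, 1, 2], size=n, p=list(spec.apoe4_probs))
    df["medication_history"] = rng.choice(
        [0, 1, 2, 3], size=n, p=list(spec.medication_history_probs)
    )
    df["medication_current"] = rng.choice(
        [0, 1, 2], size=n, p=list(spec.medication_current_probs)
    )

    prepared = design.prepare_columns(df, standardize=spec.standardize)
    for outcome, coefs in spec.coefficients.items():
        lp = np.zeros(n)
        for term, beta in coefs.items():
            lp += float(beta) * design.term_column(prepared, term)
        if not np.all(np.isfinite(lp)):
            raise ValueError(f"non-finite linear predictor for {outcome}")
        mu = np.exp(lp)
        k = spec.gamma_shape
        df[outcome] = rng.gamma(shape=k, scale=mu / k)

    for col in COHORT_COLUMNS:
        if col not in df.columns:
            raise RuntimeError(f"internal: missing cohort column {col}")
    return df[COHORT_COLUMNS]
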