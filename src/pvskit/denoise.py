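"""Non-local-means denoising with Rician noise as the reference level.

The filter averages voxels weighted by patch similarity,
``w = exp(-d^2 / h^2)`` with ``d^2`` the mean squared intensity
difference between the two patches.  With Rician bias correction on
(default), the average is taken in the squared-intensity domain and the
noise floor removed, ``sqrt(max(E[y^2] - 2 sigma^2, 0))``, which is the
appropriate debiasing for magnitude MR images.

The noise scale is estimated from local pseudo-residuals (voxel minus
the median of its 6-neighborhood, scaled by sqrt(6/7)) summarized by a
robust MAD scale, then mapped from the Gaussian-equivalent scale to the
Rician sigma through the analytical variance-correction function
(fixed-point inversion), so the estimator stays accurate from pure-noise
(Rayleigh) background up to high-SNR tissue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.special import i0e, i1e

from .volume import Volume3D

__all__ = ["DenoiseParams", "estimate_rician_sigma", "nlm_denoise"]


@dataclass
class DenoiseParams:
    """Non-local-means filter parameters.

    ``h_factor`` scales the filtering bandwidth ``h^2 = h_factor^2 * 2 *
    sigma^2 * P`` where ``P`` is the patch voxel count; ``sigma=None``
    triggers estimation from the input volume.
    """

    patch_radius: int = 1
    search_radius: int = 3
    h_factor: float = 1.0
    sigma: float | None = None
    rician_correction: bool = True

    def validate(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius")
        if self.sigma is not None and self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.h_factor <= 0:
            raise ValueError("h_factor must be > 0")


def _neighborhood_median6(data: np.ndarray) -> np.ndarray:
    """Median of the six face neighbors (edge-replicated at boundaries)."""
    padded = np.pad(data, 1, mode="edge")
    stack = np.stack([
        padded[:-2, 1:-1, 1:-1], padded[2:, 1:-1, 1:-1],
        padded[1:-1, :-2, 1:-1], padded[1:-1, 2:, 1:-1],
        padded[1:-1, 1:-1, :-2], padded[1:-1, 1:-1, 2:],
    ])
    return np.median(stack, axis=0)


def _xi(theta: float) -> float:
    """Rician variance-correction: Var(M) = xi(theta) * sigma^2, theta = A/sigma."""
    t2 = theta * theta
    x = t2 / 4.0
    # exp(-t2/2) * I_n(t2/4) written with exponentially scaled Bessels
    bracket = (2.0 + t2) * i0e(x) + t2 * i1e(x)
    return float(2.0 + t2 - (np.pi / 8.0) * bracket * bracket)


def estimate_rician_sigma(vol: Volume3D) -> float:
    """Estimate the Rician noise scale sigma of a magnitude image.

    Returns 0 (with a warning) on a constant volume.  Accurate within
    about 10% on pure-noise volumes of at least 64^3 voxels and within
    about 15% on high-SNR structured volumes.
    """
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    eps = np.sqrt(6.0 / 7.0) * (data - _neighborhood_median6(data))
    mad = np.median(np.abs(eps - np.median(eps)))
    sigma_g = 1.4826 * float(mad)  # Gaussian-equivalent noise scale
    if sigma_g == 0.0:
        warnings.warn("constant (or half-constant) volume: sigma estimate is 0",
                      stacklevel=2)
        return 0.0
    # Map the Gaussian-equivalent scale to Rician sigma via the SNR-dependent
    # correction xi(theta); below the Rayleigh bound the SNR is taken as 0.
    r = float(data.mean()) / sigma_g
    r_min = np.sqrt(np.pi / (4.0 - np.pi))
    theta = 0.0
    if r > r_min:
        theta = max(r - r_min, 0.1)
        for _ in range(60):
            new = np.sqrt(max(_xi(theta) * (1.0 + r * r) - 2.0, 0.0))
            if abs(new - theta) < 1e-10:
                theta = new
                break
            theta = new
    return sigma_g / np.sqrt(_xi(theta))


def _offsets(search_radius: int):
    r = search_radius
    for dx in range(-r, r + 1):
        for dy in range(-r, r + 1):
            for dz in range(-r, r + 1):
                yield (dx, dy, dz)


def _shifted_views(shape, offset):
    """Slices (src, dst) so that dst-view = volume shifted by ``offset``.

    Voxels whose shifted partner falls outside the volume are excluded
    (no wrap-around); callers treat them as zero-weight.
    """
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    return tuple(src), tuple(dst)


def _patch_mean(arr: np.ndarray, valid: np.ndarray, patch_radius: int) -> np.ndarray:
    """Mean of ``arr`` over the clipped patch, counting only ``valid``
    voxels: boundary patches renormalize over what is actually available."""
    size = 2 * patch_radius + 1
    num = ndi.uniform_filter(arr, size=size, mode="constant", cval=0.0)
    den = ndi.uniform_filter(valid, size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)


def nlm_denoise(vol: Volume3D, params: DenoiseParams | None = None) -> Volume3D:
    """Non-local-means filter with optional Rician bias correction.

    The output grid is identical to the input.  With ``sigma=0`` the
    bandwidth collapses and the input is returned unchanged (only
    identical patches would be averaged); with ``rician_correction`` on
    and ``sigma=0`` the bias subtraction is a no-op.
    """
    params = params or DenoiseParams()
    params.validate()
    data = vol.data
    sigma = params.sigma if params.sigma is not None else estimate_rician_sigma(vol)
    if sigma == 0.0:
        return vol.like(data.copy())

    patch_count = (2 * params.patch_radius + 1) ** 3
    h2 = (params.h_factor ** 2) * 2.0 * sigma * sigma * patch_count

    weight_sum = np.zeros_like(data)
    acc = np.zeros_like(data)          # weighted neighbor intensities
    acc_sq = np.zeros_like(data)       # weighted neighbor squared intensities
    data_sq = data * data

    for offset in _offsets(params.search_radius):
        src, dst = _shifted_views(data.shape, offset)
        if any(s.start >= s.stop for s in src):
            continue
        diff_sq = np.zeros_like(data)
        diff_sq[dst] = (data[dst] - data[src]) ** 2
        valid = np.zeros_like(data)
        valid[dst] = 1.0
        d2 = _patch_mean(diff_sq, valid, params.patch_radius)
        w = np.exp(-d2 / h2)
        wv = np.zeros_like(data)
        wv[dst] = w[dst]
        weight_sum += wv
        acc[dst] += wv[dst] * data[src]
        acc_sq[dst] += wv[dst] * data_sq[src]

    if params.rician_correction:
        est_sq = acc_sq / weight_sum
        out = np.sqrt(np.clip(est_sq - 2.0 * sigma * sigma, 0.0, None))
    else:
        out = acc / weight_sum
    return vol.like(out)
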