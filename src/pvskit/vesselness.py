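"""Multiscale Frangi vesselness and PVS mask thresholding.

The Hessian is computed by Gaussian second-derivative convolution at
each scale (in voxel units) with gamma=1 scale normalization (responses
multiplied by scale^2 so they are comparable across scales), its
eigenvalues sorted by ascending magnitude |l1| <= |l2| <= |l3|, and the
vesselness measure

    V = (1 - exp(-Ra^2 / 2 a^2)) * exp(-Rb^2 / 2 b^2) * (1 - exp(-S^2 / 2 c^2))

with Ra = |l2|/|l3| (plate vs line), Rb = |l1|/sqrt(|l2 l3|) (blobness)
and S the Frobenius norm of the Hessian (structureness), evaluated only
where the polarity sign condition holds (dark tubes on a bright
background: l2 > 0 and l3 > 0).  The multiscale map is the maximum over
scales; thresholding it yields the binary PVS mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .volume import Volume3D

__all__ = [
    "FrangiParams",
    "VesselnessMap",
    "default_scales",
    "hessian_eigenvalues",
    "frangi_vesselness",
    "threshold_mask",
]


def default_scales(n: int = 5, lo: float = 0.1, hi: float = 5.0) -> list[float]:
    """Logarithmically spaced Gaussian scales (voxels) spanning [lo, hi].

    The sub-voxel end of the default range (0.1 voxel) behaves nearly as
    an unsmoothed finite-difference Hessian; it is kept because thin PVS
    are at or below voxel scale.
    """
    return [float(s) for s in np.geomspace(lo, hi, n)]


@dataclass
class FrangiParams:
    """Frangi filter sensitivities and scale sampling.

    ``c="auto"`` sets the structureness scale per Gaussian scale to half
    the maximum Hessian Frobenius norm over the volume (the standard
    data-driven choice); ``polarity`` selects which intensity contrast
    counts as a tube.
    """

    scales: list[float] = field(default_factory=default_scales)
    alpha: float = 0.5
    beta: float = 0.5
    c: float | str = "auto"
    polarity: str = "dark-tubes"
    threshold: float = 0.00001

    def validate(self) -> None:
        if not self.scales:
            raise ValueError("scale list must not be empty")
        if any(s <= 0 for s in self.scales):
            raise ValueError("all scales must be > 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.polarity not in ("dark-tubes", "bright-tubes"):
            raise ValueError("polarity must be 'dark-tubes' or 'bright-tubes'")
        if not (isinstance(self.c, str) and self.c == "auto") and float(self.c) <= 0:
            raise ValueError("c must be > 0 or 'auto'")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class VesselnessMap:
    """Per-voxel vesselness in [0,1] with the argmax scale per voxel."""

    values: np.ndarray
    best_scale: np.ndarray
    scales: list[float]


_ORDERS = [(2, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (1, 0, 1), (0, 1, 1)]


def gaussian_derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """1D Gaussian-derivative correlation kernel with exact discrete moments.

    The sampled Gaussian is normalized to unit sum; derivative kernels
    are moment-corrected so that constants map exactly to 0, linear
    ramps have derivative exactly 1 (order 1), and quadratics have
    second derivative exactly 2 (order 2).  At sub-voxel sigma the
    kernels degrade gracefully to central finite differences.
    """
    radius = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -(x / sigma**2) * phi
        return k / np.sum(k * x)
    if order == 2:
        k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
        k[radius] -= k.sum()           # annihilate constants exactly
        return k * (2.0 / np.sum(k * x * x))
    raise ValueError(f"unsupported derivative order {order}")


def hessian_eigenvalues(vol: Volume3D, scale: float) -> np.ndarray:
    """Scale-normalized Hessian eigenvalues, sorted by |eigenvalue|.

    Returns an array of shape ``vol.shape + (3,)`` with
    ``|l1| <= |l2| <= |l3|`` along the last axis.  Derivatives are taken
    in voxel units at Gaussian scale ``scale`` and multiplied by
    ``scale**2`` (gamma=1 normalization).
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    data = vol.data
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values")
    kernels = {o: gaussian_derivative_kernel(scale, o) for o in (0, 1, 2)}
    h = {}
    for order in _ORDERS:
        arr = data
        for axis, o in enumerate(order):
            arr = ndi.correlate1d(arr, kernels[o], axis=axis, mode="reflect")
        h[order] = arr
    H = np.empty(data.shape + (3, 3))
    H[..., 0, 0] = h[(2, 0, 0)]
    H[..., 1, 1] = h[(0, 2, 0)]
    H[..., 2, 2] = h[(0, 0, 2)]
    H[..., 0, 1] = H[..., 1, 0] = h[(1, 1, 0)]
    H[..., 0, 2] = H[..., 2, 0] = h[(1, 0, 1)]
    H[..., 1, 2] = H[..., 2, 1] = h[(0, 1, 1)]
    H *= scale * scale
    eig = np.linalg.eigvalsh(H)  # ascending by value
    order = np.argsort(np.abs(eig), axis=-1, kind="stable")
    return np.take_along_axis(eig, order, axis=-1)


def _vesselness_single_scale(eig: np.ndarray, params: FrangiParams) -> np.ndarray:
    l1, l2, l3 = eig[..., 0], eig[..., 1], eig[..., 2]
    if params.polarity == "dark-tubes":
        sign_ok = (l2 > 0) & (l3 > 0)
    else:
        sign_ok = (l2 < 0) & (l3 < 0)
    a2, a3 = np.abs(l2), np.abs(l3)
    S2 = l1 * l1 + l2 * l2 + l3 * l3
    if isinstance(params.c, str):
        c = 0.5 * float(np.sqrt(S2.max()))
    else:
        c = float(params.c)
    if c == 0.0:
        return np.zeros_like(l1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ra2 = np.where(a3 > 0, (a2 / np.maximum(a3, 1e-300)) ** 2, 0.0)
        Rb2 = np.where(a2 * a3 > 0, (l1 * l1) / np.maximum(a2 * a3, 1e-300), 0.0)
    v = (
        (1.0 - np.exp(-Ra2 / (2.0 * params.alpha ** 2)))
        * np.exp(-Rb2 / (2.0 * params.beta ** 2))
        * (1.0 - np.exp(-S2 / (2.0 * c * c)))
    )
    return np.where(sign_ok, v, 0.0)


def frangi_vesselness(vol: Volume3D, params: FrangiParams | None = None) -> VesselnessMap:
    """Multiscale Frangi vesselness: per-voxel maximum over scales."""
    params = params or FrangiParams()
    params.validate()
    best = np.zeros(vol.shape)
    best_scale = np.full(vol.shape, params.scales[0], dtype=float)
    for scale in params.scales:
        eig = hessian_eigenvalues(vol, scale)
        v = _vesselness_single_scale(eig, params)
        better = v > best
        best = np.where(better, v, best)
        best_scale = np.where(better, scale, best_scale)
    return VesselnessMap(values=best, best_scale=best_scale, scales=list(params.scales))


def threshold_mask(vmap: VesselnessMap, threshold: float) -> np.ndarray:
    """Binary PVS mask: true where vesselness >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return vmap.values >= threshold
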