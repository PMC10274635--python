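"""Independent reference implementations used only as test oracles.

Each oracle recomputes a quantity through a different mechanism than the
production code: explicit nested-loop convolution with closed-form
derivative-of-Gaussian kernels plus a trigonometric symmetric 3x3
eigen-solve for vesselness; a literal quadruple loop for non-local
means; direct numerical maximization of the Gamma log-likelihood for the
GLM.  They are deliberately slow and simple.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


# ---------------------------------------------------------------------------
# Brute-force multiscale vesselness
# ---------------------------------------------------------------------------

def _gaussian_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian kernel and its moment-corrected derivatives.

    The base kernel is the sampled Gaussian normalized to unit sum;
    derivative kernels are rescaled/offset so the discrete moments are
    exact (constants -> 0, d/dx x = 1, d2/dx2 x^2 = 2), mirroring the
    production convention through an independent code path.
    """
    radius = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(-radius, radius + 1, dtype=float)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -(x / sigma**2) * phi
        return k / float(sum(ki * xi for ki, xi in zip(k, x)))
    if order == 2:
        k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
        k[radius] -= float(k.sum())
        return k * (2.0 / float(sum(ki * xi * xi for ki, xi in zip(k, x))))
    raise ValueError(order)


def _reflect_index(i: int, n: int) -> int:
    # scipy 'reflect' boundary: (d c b a | a b c d | d c b a)
    period = 2 * n
    i = i % period
    if i < 0:
        i += period
    return i if i < n else period - 1 - i


def _convolve_axis_explicit(data: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    """Correlation along one axis with explicit index arithmetic."""
    radius = (len(kernel) - 1) // 2
    out = np.zeros_like(data)
    moved = np.moveaxis(data, axis, 0)
    out_m = np.moveaxis(out, axis, 0)
    n = moved.shape[0]
    for i in range(n):
        acc = np.zeros(moved.shape[1:])
        for k in range(-radius, radius + 1):
            acc += kernel[k + radius] * moved[_reflect_index(i + k, n)]
        out_m[i] = acc
    return out


def _eig_sym3_trig(m: np.ndarray) -> np.ndarray:
    """Closed-form (trigonometric) eigenvalues of a symmetric 3x3 matrix."""
    a, b, c = m[0, 0], m[1, 1], m[2, 2]
    d, e, f = m[0, 1], m[0, 2], m[1, 2]
    p1 = d * d + e * e + f * f
    q = (a + b + c) / 3.0
    if p1 == 0.0:
        return np.sort(np.array([a, b, c]))
    p2 = (a - q) ** 2 + (b - q) ** 2 + (c - q) ** 2 + 2.0 * p1
    p = np.sqrt(p2 / 6.0)
    B = (m - q * np.eye(3)) / p
    r = np.linalg.det(B) / 2.0
    r = min(1.0, max(-1.0, r))
    phi = np.arccos(r) / 3.0
    e1 = q + 2.0 * p * np.cos(phi)
    e3 = q + 2.0 * p * np.cos(phi + 2.0 * np.pi / 3.0)
    e2 = 3.0 * q - e1 - e3
    return np.sort(np.array([e1, e2, e3]))


def brute_force_vesselness(data: np.ndarray, scales, alpha=0.5, beta=0.5,
                           c="auto", polarity="dark-tubes") -> np.ndarray:
    """Reference multiscale Frangi vesselness by explicit convolution and
    per-voxel closed-form eigen-solve."""
    data = np.asarray(data, dtype=float)
    best = np.zeros(data.shape)
    orders = {
        (0, 0): (2, 0, 0), (1, 1): (0, 2, 0), (2, 2): (0, 0, 2),
        (0, 1): (1, 1, 0), (0, 2): (1, 0, 1), (1, 2): (0, 1, 1),
    }
    for scale in scales:
        H = np.zeros(data.shape + (3, 3))
        for (i, j), order in orders.items():
            arr = data
            for axis, o in enumerate(order):
                arr = _convolve_axis_explicit(arr, _gaussian_kernel(scale, o), axis)
            H[..., i, j] = arr
            H[..., j, i] = arr
        H *= scale * scale
        # per-voxel eigen-solve, sorted by |eigenvalue|
        v = np.zeros(data.shape)
        S2_all = np.einsum("...ij,...ij->...", H, H)
        c_val = 0.5 * np.sqrt(S2_all.max()) if isinstance(c, str) else float(c)
        if c_val == 0.0:
            continue
        for idx in np.ndindex(data.shape):
            eig = _eig_sym3_trig(H[idx])
            eig = eig[np.argsort(np.abs(eig), kind="stable")]
            l1, l2, l3 = eig
            if polarity == "dark-tubes":
                if not (l2 > 0 and l3 > 0):
                    continue
            else:
                if not (l2 < 0 and l3 < 0):
                    continue
            a2, a3 = abs(l2), abs(l3)
            if a3 == 0:
                continue
            ra2 = (a2 / a3) ** 2
            rb2 = (l1 * l1) / (a2 * a3) if a2 * a3 > 0 else 0.0
            s2 = l1 * l1 + l2 * l2 + l3 * l3
            v[idx] = ((1.0 - np.exp(-ra2 / (2 * alpha**2)))
                      * np.exp(-rb2 / (2 * beta**2))
                      * (1.0 - np.exp(-s2 / (2 * c_val**2))))
        best = np.maximum(best, v)
    return best


# ---------------------------------------------------------------------------
# Reference non-local means (literal loops)
# ---------------------------------------------------------------------------

def nlm_reference(data: np.ndarray, sigma: float, patch_radius=1, search_radius=2,
                  h_factor=1.0, rician_correction=False) -> np.ndarray:
    """Quadruple-loop NLM with clipped-patch renormalization."""
    data = np.asarray(data, dtype=float)
    nx, ny, nz = data.shape
    P = (2 * patch_radius + 1) ** 3
    h2 = h_factor**2 * 2.0 * sigma * sigma * P
    out = np.zeros_like(data)

    def inside(p):
        return all(0 <= p[i] < data.shape[i] for i in range(3))

    rng_s = range(-search_radius, search_radius + 1)
    rng_p = range(-patch_radius, patch_radius + 1)
    for vx in range(nx):
        for vy in range(ny):
            for vz in range(nz):
                wsum = 0.0
                acc = 0.0
                acc2 = 0.0
                for tx in rng_s:
                    for ty in rng_s:
                        for tz in rng_s:
                            nb = (vx + tx, vy + ty, vz + tz)
                            if not inside(nb):
                                continue
                            d2 = 0.0
                            cnt = 0
                            for px in rng_p:
                                for py in rng_p:
                                    for pz in rng_p:
                                        u = (vx + px, vy + py, vz + pz)
                                        ut = (u[0] + tx, u[1] + ty, u[2] + tz)
                                        if inside(u) and inside(ut):
                                            diff = data[u] - data[ut]
                                            d2 += diff * diff
                                            cnt += 1
                            w = np.exp(-(d2 / cnt) / h2) if cnt else 0.0
                            wsum += w
                            acc += w * data[nb]
                            acc2 += w * data[nb] ** 2
                if rician_correction:
                    out[vx, vy, vz] = np.sqrt(max(acc2 / wsum - 2 * sigma * sigma, 0.0))
                else:
                    out[vx, vy, vz] = acc / wsum
    return out


# ---------------------------------------------------------------------------
# Direct Gamma/log-link likelihood maximization
# ---------------------------------------------------------------------------

def fit_gamma_direct(X, y, b0=None) -> np.ndarray:
    """Maximize the Gamma/log-link log-likelihood numerically.

    For fixed shape the maximizing coefficients are independent of the
    shape, so the unit-shape kernel sum(-y*exp(-eta) - eta) is maximized
    with BFGS from a deliberately perturbed start.
    """
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)

    def negll(b):
        eta = Xm @ b
        return float(np.sum(yv * np.exp(-eta) + eta))

    def grad(b):
        eta = Xm @ b
        return Xm.T @ (1.0 - yv * np.exp(-eta))

    def hess(b):
        eta = Xm @ b
        w = yv * np.exp(-eta)
        return Xm.T @ (w[:, None] * Xm)

    if b0 is None:
        ols = np.linalg.lstsq(Xm, np.log(yv), rcond=None)[0]
        b0 = ols * 1.05 + 1e-3  # deliberately off the solution
    res = minimize(negll, b0, jac=grad, hess=hess, method="Newton-CG",
                   options={"xtol": 1e-14, "maxiter": 500})
    # polish with a few full Newton steps (the objective is convex)
    b = res.x
    for _ in range(50):
        step = np.linalg.solve(hess(b), grad(b))
        b = b - step
        if np.max(np.abs(step)) < 1e-13:
            break
    return b
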