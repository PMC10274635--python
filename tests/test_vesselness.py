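"""Hessian eigenvalue and Frangi vesselness contracts, including the
brute-force oracle equivalence on small volumes."""

import numpy as np
import pytest

from pvskit.vesselness import (
    FrangiParams,
    default_scales,
    frangi_vesselness,
    hessian_eigenvalues,
    threshold_mask,
)
from pvskit.volume import Volume3D

from _oracles import brute_force_vesselness


def _cylinder(shape=(40, 40, 40), radius=2.0, value=30.0, background=100.0, axis=2):
    img = np.full(shape, background)
    axes = [i for i in range(3) if i != axis]
    grids = np.meshgrid(*[np.arange(shape[i]) for i in axes], indexing="ij")
    d = np.sqrt(sum((g - shape[i] / 2 + 0.5) ** 2 for g, i in zip(grids, axes)))
    mask2d = d <= radius
    img_moved = np.moveaxis(img, axis, -1)
    img_moved[mask2d, :] = value
    return np.moveaxis(img_moved, -1, axis)


class TestHessianEigenvalues:
    def test_constant_volume_all_zero(self, constant_volume):
        eig = hessian_eigenvalues(constant_volume, scale=1.0)
        assert np.allclose(eig, 0.0, atol=1e-12)

    def test_separable_quadratic_closed_form(self):
        """I(x,y,z) = x^2 has Hessian diag(2,0,0); with gamma=1 scale
        normalization the dominant eigenvalue is 2*scale^2."""
        n = 32
        x = np.arange(n, dtype=float)
        img = np.broadcast_to((x**2)[:, None, None], (n, n, n)).copy()
        scale = 1.5
        eig = hessian_eigenvalues(Volume3D(img), scale=scale)
        interior = eig[10:-10, 10:-10, 10:-10]
        np.testing.assert_allclose(interior[..., 0], 0.0, atol=1e-6)
        np.testing.assert_allclose(interior[..., 1], 0.0, atol=1e-6)
        np.testing.assert_allclose(interior[..., 2], 2.0 * scale**2, rtol=1e-6)

    def test_eigenvalues_sorted_by_magnitude(self, rng):
        vol = Volume3D(rng.normal(0, 1, (12, 12, 12)))
        eig = hessian_eigenvalues(vol, scale=1.0)
        mags = np.abs(eig)
        assert np.all(mags[..., 0] <= mags[..., 1] + 1e-15)
        assert np.all(mags[..., 1] <= mags[..., 2] + 1e-15)

    def test_dark_cylinder_axis_signature(self):
        """On the axis of a dark tube: l1 ~ 0, l2 ~ l3 > 0 at scale ~ radius."""
        img = _cylinder(radius=2.0)
        eig = hessian_eigenvalues(Volume3D(img), scale=2.0)
        c = eig[19, 19, 10:30]  # on-axis voxels
        l1, l2, l3 = c[..., 0], c[..., 1], c[..., 2]
        assert np.all(l2 > 0) and np.all(l3 > 0)
        assert np.median(np.abs(l1)) < 0.15 * np.median(l3)
        assert np.median(l2 / l3) > 0.8

    def test_nonpositive_scale_rejected(self, constant_volume):
        with pytest.raises(ValueError):
            hessian_eigenvalues(constant_volume, scale=0.0)


class TestFrangiVesselness:
    def test_constant_volume_zero_everywhere(self, constant_volume):
        vmap = frangi_vesselness(constant_volume, FrangiParams(scales=[1.0, 2.0]))
        assert np.all(vmap.values == 0.0)

    def test_values_in_unit_interval(self, rng):
        vol = Volume3D(rng.normal(100, 15, (20, 20, 20)))
        vmap = frangi_vesselness(vol, FrangiParams(scales=[0.8, 1.6]))
        assert vmap.values.min() >= 0.0
        assert vmap.values.max() <= 1.0

    def test_bright_cylinder_fails_dark_polarity(self):
        img = _cylinder(value=170.0, background=100.0)
        vmap = frangi_vesselness(Volume3D(img), FrangiParams(scales=[2.0]))
        assert np.all(vmap.values[19, 19, 10:30] < 1e-12)

    def test_cylinder_beats_plate(self):
        """The plate-vs-line ratio suppresses sheet structures."""
        cyl = _cylinder(radius=2.0)
        plate = np.full((40, 40, 40), 100.0)
        plate[:, 19:21, :] = 30.0
        p = FrangiParams(scales=[2.0])
        v_cyl = frangi_vesselness(Volume3D(cyl), p).values
        v_plate = frangi_vesselness(Volume3D(plate), p).values
        assert (np.median(v_cyl[19, 19, 10:30])
                > np.median(v_plate[10:30, 19:21, 10:30]))

    def test_polarity_inversion_symmetry(self, rng):
        img = rng.normal(100, 10, (20, 20, 20))
        p_dark = FrangiParams(scales=[1.0, 2.0], polarity="dark-tubes")
        p_bright = FrangiParams(scales=[1.0, 2.0], polarity="bright-tubes")
        v1 = frangi_vesselness(Volume3D(img), p_dark).values
        v2 = frangi_vesselness(Volume3D(-img), p_bright).values
        np.testing.assert_allclose(v1, v2, atol=1e-6)

    def test_adding_scales_never_decreases_response(self, rng):
        img = rng.normal(100, 10, (18, 18, 18))
        v_small = frangi_vesselness(Volume3D(img), FrangiParams(scales=[1.0])).values
        v_more = frangi_vesselness(Volume3D(img),
                                   FrangiParams(scales=[1.0, 2.0, 3.0])).values
        assert np.all(v_more >= v_small - 1e-15)

    def test_rotation_robustness_of_axis_response(self):
        """Grid-aligned vs 45-degree oblique cylinder at matched scale."""
        n = 48
        coords = np.stack(np.meshgrid(*[np.arange(n, dtype=float)] * 3,
                                      indexing="ij"), axis=-1) - (n / 2 - 0.5)
        radius = 2.0

        def render(axis_dir):
            axis_dir = np.asarray(axis_dir) / np.linalg.norm(axis_dir)
            proj = coords @ axis_dir
            d = np.linalg.norm(coords - proj[..., None] * axis_dir, axis=-1)
            img = np.full((n, n, n), 100.0)
            img[d <= radius] = 30.0
            return img, d

        p = FrangiParams(scales=[2.0])
        responses = []
        for axis_dir in ([0, 0, 1], [1, 1, 0]):
            img, d = render(axis_dir)
            v = frangi_vesselness(Volume3D(img), p).values
            core = (d <= 0.75) & (np.abs(coords).max(axis=-1) < n / 2 - 8)
            responses.append(np.median(v[core]))
        lo, hi = sorted(responses)
        assert (hi - lo) / hi < 0.2

    def test_empty_scale_list_rejected(self, constant_volume):
        with pytest.raises(ValueError):
            frangi_vesselness(constant_volume, FrangiParams(scales=[]))

    def test_matches_brute_force_oracle(self, rng):
        """Production path equals explicit convolution + closed-form
        per-voxel eigen-solve on a small volume."""
        img = rng.normal(1.0, 0.1, (12, 12, 12))
        scales = [0.8, 1.5]
        p = FrangiParams(scales=scales)
        v_prod = frangi_vesselness(Volume3D(img), p).values
        v_ref = brute_force_vesselness(img, scales)
        np.testing.assert_allclose(v_prod, v_ref, atol=1e-8)


class TestThresholdMask:
    def test_threshold_conventions(self):
        from pvskit.vesselness import VesselnessMap
        values = np.array([[[0.0, 0.5, 1e-5, 9.9e-6]]])
        vmap = VesselnessMap(values=values, best_scale=np.ones_like(values), scales=[1.0])
        mask = threshold_mask(vmap, 1e-5)
        # >= convention: exactly-at-threshold voxels are included
        assert mask.tolist() == [[[False, True, True, False]]]
        assert not threshold_mask(vmap, 0.9).any()
        with pytest.raises(ValueError):
            threshold_mask(vmap, 1.5)

    def test_default_scales_span_published_range(self):
        s = default_scales()
        assert s[0] == pytest.approx(0.1)
        assert s[-1] == pytest.approx(5.0)
        assert len(s) == 5
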