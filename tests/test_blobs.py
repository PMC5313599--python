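import numpy as np
import pytest

import localroi as lr
from localroi.blobs import gaussian_profile


class TestKernel:
    def test_length_rule(self):
        # ceil(6 sigma + 1), forced odd
        assert len(lr.gaussian_kernel(2.0)) == 13
        assert len(lr.gaussian_kernel(1.5)) == 11  # ceil(10) -> 10 -> odd 11
        for s in [0.7, 1.0, 3.3, 8.0]:
            n = len(lr.gaussian_kernel(s))
            assert n % 2 == 1 and n >= int(np.ceil(6 * s + 1))

    def test_center_value(self):
        k = lr.gaussian_kernel(1.0)
        assert np.isclose(k[len(k) // 2], 1.0 / np.sqrt(2 * np.pi), atol=1e-6)

    def test_even_symmetry(self):
        for s in [1.0, 2.5]:
            k = lr.gaussian_kernel(s)
            assert np.array_equal(k, k[::-1])

    def test_profile_is_unnormalized_kernel(self):
        s = 2.0
        assert np.allclose(gaussian_profile(s), lr.gaussian_kernel(s) * s * np.sqrt(2 * np.pi))

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            lr.gaussian_kernel(0.0)


class TestBuildBasis:
    def test_single_band_lattice_count(self):
        geom = lr.LocalGeometry(n_roi=272, n_ext=572, n_angles=4)
        basis = lr.build_basis(geom, 20.0, multiresolution=False)  # s = 13
        assert basis.n_coeffs == 44**2

    def test_spacing_factor(self):
        assert np.isclose(lr.blobs.SPACING_FACTOR, 0.65)

    def test_multiresolution_fewer_coeffs(self):
        geom = lr.LocalGeometry(n_roi=272, n_ext=572, n_angles=4)
        single = lr.build_basis(geom, 20.0, multiresolution=False)
        multi = lr.build_basis(geom, 20.0, multiresolution=True)
        assert multi.n_coeffs < single.n_coeffs

    def test_sigma_doubles_per_band(self):
        geom = lr.LocalGeometry(n_roi=64, n_ext=160, n_angles=4)
        basis = lr.build_basis(geom, 3.0)
        uncapped = basis.sigmas[basis.sigmas < geom.n_roi]
        assert np.allclose(uncapped, 3.0 * 2.0 ** np.arange(len(uncapped)))
        assert np.all(basis.sigmas <= geom.n_roi)  # capped at ROI diameter

    def test_band_membership_by_radius(self):
        geom = lr.LocalGeometry(n_roi=64, n_ext=160, n_angles=4)
        basis = lr.build_basis(geom, 3.0)
        c = (160 - 1) / 2.0
        r_in = 0.0
        for b, r_out in enumerate(basis.band_radii):
            pts = basis.band_centers(b)
            d = np.hypot(pts[:, 0] - c, pts[:, 1] - c)
            # rounding to the pixel grid may move a center by up to 1/sqrt(2)
            assert np.all(d >= r_in - 1.0) and np.all(d < r_out + 1.0)
            r_in = r_out

    def test_oversized_sigma_rejected(self):
        geom = lr.LocalGeometry(n_roi=16, n_ext=16, n_angles=4)
        with pytest.raises(ValueError):
            lr.build_basis(geom, 1e5, multiresolution=False)


def blob_sum_oracle(basis, coeffs):
    """Explicit sum over blobs with per-pixel kernel evaluation."""
    n = basis.n_ext
    out = np.zeros((n, n))
    for b in range(basis.n_bands):
        k = basis.kernel(b)
        p = gaussian_profile(basis.sigmas[b])
        half = (len(k) - 1) // 2
        for (r0, c0), c in zip(basis.band_centers(b), coeffs[basis.band_slices[b]]):
            for dr in range(-half, half + 1):
                r = r0 + dr
                if not 0 <= r < n:
                    continue
                for dc in range(-half, half + 1):
                    col = c0 + dc
                    if 0 <= col < n:
                        out[r, col] += c * k[dr + half] * p[dc + half]
    return out


class TestSynthesizeAnalyze:
    def test_single_blob_is_kernel(self):
        geom = lr.LocalGeometry(n_roi=32, n_ext=33, n_angles=4)
        basis = lr.build_basis(geom, 2.0, multiresolution=False)
        # blob closest to the support center
        d = np.hypot(basis.centers[:, 0] - 16, basis.centers[:, 1] - 16)
        i = int(np.argmin(d))
        c = np.zeros(basis.n_coeffs)
        c[i] = 1.0
        img = lr.synthesize(basis, c)
        k2d = np.outer(lr.gaussian_kernel(2.0), gaussian_profile(2.0))
        r0, c0 = basis.centers[i]
        half = (k2d.shape[0] - 1) // 2
        patch = img[r0 - half : r0 + half + 1, c0 - half : c0 + half + 1]
        assert np.allclose(patch, k2d, atol=1e-12)
        # Eq.-style single 2-D prefactor
        assert np.isclose(img[r0, c0], 1.0 / (2.0 * np.sqrt(2 * np.pi)))

    def test_matches_blob_sum_oracle(self, rng):
        geom = lr.LocalGeometry(n_roi=24, n_ext=30, n_angles=4)
        basis = lr.build_basis(geom, 3.0)
        c = rng.normal(size=basis.n_coeffs)
        assert np.max(np.abs(lr.synthesize(basis, c) - blob_sum_oracle(basis, c))) <= 1e-6

    def test_linearity(self, rng):
        geom = lr.LocalGeometry(n_roi=24, n_ext=30, n_angles=4)
        basis = lr.build_basis(geom, 3.0)
        c1 = rng.normal(size=basis.n_coeffs)
        c2 = rng.normal(size=basis.n_coeffs)
        assert np.allclose(
            lr.synthesize(basis, c1 + c2),
            lr.synthesize(basis, c1) + lr.synthesize(basis, c2),
        )

    def test_adjoint_identity(self, rng):
        geom = lr.LocalGeometry(n_roi=24, n_ext=40, n_angles=4)
        basis = lr.build_basis(geom, 2.5)
        c = rng.normal(size=basis.n_coeffs)
        x = rng.normal(size=(40, 40))
        lhs = np.vdot(lr.synthesize(basis, c), x)
        rhs = np.vdot(c, lr.analyze(basis, x))
        assert abs(lhs - rhs) <= 1e-6 * abs(lhs)

    def test_zero_cases(self):
        geom = lr.LocalGeometry(n_roi=24, n_ext=30, n_angles=4)
        basis = lr.build_basis(geom, 3.0)
        assert np.all(lr.synthesize(basis, np.zeros(basis.n_coeffs)) == 0)
        assert np.all(lr.analyze(basis, np.zeros((30, 30))) == 0)

    def test_length_mismatch(self):
        geom = lr.LocalGeometry(n_roi=24, n_ext=30, n_angles=4)
        basis = lr.build_basis(geom, 3.0)
        with pytest.raises(ValueError):
            lr.synthesize(basis, np.zeros(basis.n_coeffs + 1))

    def test_near_basis_gram_conditioning(self):
        # with s = 0.65 sigma neighboring blobs overlap strongly yet stay
        # linearly independent: the 5x5-patch Gram matrix is positive
        # definite with a bounded condition number
        geom = lr.LocalGeometry(n_roi=40, n_ext=41, n_angles=4)
        basis = lr.build_basis(geom, 3.0, multiresolution=False)
        c0 = (41 - 1) / 2.0
        d = np.hypot(basis.centers[:, 0] - c0, basis.centers[:, 1] - c0)
        idx = np.argsort(d)[:25]
        cols = []
        for i in idx:
            e = np.zeros(basis.n_coeffs)
            e[i] = 1.0
            cols.append(lr.synthesize(basis, e).ravel())
        G = np.array(cols) @ np.array(cols).T
        w = np.linalg.eigvalsh(G)
        # strongly overlapping but linearly independent: positive definite
        # with a finite (if large) condition number
        assert w.min() > 1e-9 * w.max()
        assert w.max() / w.min() < 1e8


class TestKnownZoneRestriction:
    def _setup(self):
        ph = lr.make_shepp_logan(64)
        setup = lr.make_local_setup(ph, 32, 8)
        basis = lr.build_basis(setup.geom, 3.0)
        return setup, basis

    def test_zero_coeffs(self):
        setup, basis = self._setup()
        vals = lr.restrict_to_known_zone(basis, np.zeros(basis.n_coeffs), setup.zone, setup.geom)
        assert vals.shape == (setup.zone.size,)
        assert np.all(vals == 0)

    def test_equals_crop_then_mask_of_synthesis(self, rng):
        setup, basis = self._setup()
        c = rng.normal(size=basis.n_coeffs)
        vals = lr.restrict_to_known_zone(basis, c, setup.zone, setup.geom)
        img = lr.crop_image(lr.synthesize(basis, c), setup.geom.n_roi)
        assert np.allclose(vals, img[setup.zone.rows, setup.zone.cols], atol=1e-10)

    def test_masked_operator_adjoint(self, rng):
        setup, basis = self._setup()
        M = lr.zone_matrix(basis, setup.zone, setup.geom)
        c = rng.normal(size=basis.n_coeffs)
        y = rng.normal(size=setup.zone.size)
        assert np.isclose(np.vdot(M @ c, y), np.vdot(c, M.T @ y))
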