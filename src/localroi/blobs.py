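"""Multi-resolution Gaussian blob basis for the low-frequency correction term.

The reconstruction error of a padded-FBP interior reconstruction is mostly a
smooth, low-frequency bias (the cupping artifact).  It is therefore fitted in
a coarse basis of truncated 2-D Gaussians placed on a lattice: the synthesis
operator G maps a coefficient vector to an image, and the fit has far fewer
unknowns than the extended pixel grid.

The 1-D profile is ``g(t) = exp(-t^2 / (2 sigma^2)) / (sigma sqrt(2 pi))``,
truncated at 3 sigma (length ``ceil(6 sigma + 1)``, forced odd); the 2-D blob
is its outer product (separability).  Blobs are spaced ``s = 0.65 sigma``
apart.  In the multi-resolution variant the standard deviation doubles from
band to band away from the ROI: fine blobs resolve the correction inside the
region of interest while coarse blobs soak up the contribution of the
exterior, which only needs to be represented roughly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.sparse

__all__ = [
    "GaussianBasisSpec",
    "gaussian_kernel",
    "build_basis",
    "synthesize",
    "analyze",
    "zone_matrix",
    "restrict_to_known_zone",
    "SPACING_FACTOR",
]

#: Lattice spacing as a fraction of the blob standard deviation.
SPACING_FACTOR = 0.65


def gaussian_kernel(sigma: float) -> np.ndarray:
    """1-D Gaussian samples on integer offsets, truncated at +-3 sigma.

    The length is ``ceil(6 sigma + 1)``, forced odd so that blobs are
    centered on a sample.  The normalization is ``1/(sigma sqrt(2 pi))`` at
    the center.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    length = int(np.ceil(6.0 * sigma + 1.0))
    if length % 2 == 0:
        length += 1
    half = (length - 1) // 2
    t = np.arange(-half, half + 1, dtype=np.float64)
    return np.exp(-(t**2) / (2.0 * sigma**2)) / (sigma * np.sqrt(2.0 * np.pi))


def gaussian_profile(sigma: float) -> np.ndarray:
    """Unnormalized 1-D profile ``exp(-t^2 / (2 sigma^2))``, truncated like
    :func:`gaussian_kernel`.

    The 2-D blob carries a single ``1/(sigma sqrt(2 pi))`` prefactor, so it
    factors as ``gaussian_kernel`` along one axis times this profile along
    the other; the profile is also the blob's own projection onto a detector
    row, used for the sinogram row convolutions.
    """
    return gaussian_kernel(sigma) * (sigma * np.sqrt(2.0 * np.pi))


@dataclass
class GaussianBasisSpec:
    """Blob centers, per-band standard deviations and band bookkeeping.

    ``centers`` are pixel positions on the N2^2 extended support (lattice
    positions rounded to the pixel grid, so synthesis is an exact scatter
    followed by a convolution).  Band ``j`` owns the coefficient slice
    ``band_slices[j]`` and uses standard deviation ``sigmas[j]``.
    """

    n_ext: int
    centers: np.ndarray  # (n_coeffs, 2) int rows/cols
    sigmas: np.ndarray  # per band
    band_slices: list[slice]
    band_radii: np.ndarray  # outer radius of each band (inf for the last)
    spacing_factor: float = SPACING_FACTOR
    _kernels: list[np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]
    _profiles: list[np.ndarray] = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.centers = np.asarray(self.centers)
        self.sigmas = np.asarray(self.sigmas, dtype=np.float64)
        if self._kernels is None:
            self._kernels = [gaussian_kernel(s) for s in self.sigmas]
        if self._profiles is None:
            self._profiles = [gaussian_profile(s) for s in self.sigmas]

    @property
    def n_coeffs(self) -> int:
        return int(self.centers.shape[0])

    @property
    def n_bands(self) -> int:
        return len(self.band_slices)

    def kernel(self, band: int) -> np.ndarray:
        return self._kernels[band]

    def profile(self, band: int) -> np.ndarray:
        return self._profiles[band]

    def band_centers(self, band: int) -> np.ndarray:
        return self.centers[self.band_slices[band]]


def _band_lattice(n_ext: int, spacing: float) -> np.ndarray:
    """Centered regular lattice of spacing ``s`` covering the support.

    ``ceil(n_ext / s)`` points per axis, centered on ``(n_ext - 1) / 2``.
    """
    m = int(np.ceil(n_ext / spacing))
    k = np.arange(m, dtype=np.float64)
    pos = (n_ext - 1) / 2.0 + (k - (m - 1) / 2.0) * spacing
    rr, cc = np.meshgrid(pos, pos, indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def build_basis(
    geom,
    sigma0: float,
    multiresolution: bool = True,
    cap: str = "diameter",
) -> GaussianBasisSpec:
    """Lay out the Gaussian basis on the extended support.

    Single-resolution: one lattice of spacing ``0.65 sigma0`` covering the
    whole N2^2 support.  Multi-resolution: coefficients are classified by
    distance to the ROI center into concentric bands; band 0 is the ROI disk
    with standard deviation ``sigma0``, and each further band doubles both
    its outer radius and its standard deviation.  The doubling is capped once
    sigma reaches the ROI diameter (``cap="diameter"``, default) or radius
    (``cap="radius"``); beyond the cap sigma stays constant.
    """
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    n_ext = geom.n_ext
    if SPACING_FACTOR * sigma0 > n_ext:
        raise ValueError("sigma0 too large: no blob center fits the support")
    center = (n_ext - 1) / 2.0
    if not multiresolution:
        lattice = _band_lattice(n_ext, SPACING_FACTOR * sigma0)
        centers = np.rint(lattice).astype(np.intp)
        return GaussianBasisSpec(
            n_ext=n_ext,
            centers=centers,
            sigmas=np.array([sigma0]),
            band_slices=[slice(0, len(centers))],
            band_radii=np.array([np.inf]),
        )

    if cap == "diameter":
        sigma_cap = float(geom.n_roi)
    elif cap == "radius":
        sigma_cap = geom.n_roi / 2.0
    else:
        raise ValueError("cap must be 'diameter' or 'radius'")

    roi_radius = geom.n_roi / 2.0
    max_radius = np.hypot(center, center)  # distance to support corner
    sigmas, radii = [], []
    j = 0
    while True:
        sigmas.append(min(sigma0 * 2.0**j, sigma_cap))
        r_out = roi_radius * 2.0**j
        if r_out >= max_radius:
            radii.append(np.inf)
            break
        radii.append(r_out)
        j += 1

    centers_list, band_slices = [], []
    start = 0
    r_in = 0.0
    for sig, r_out in zip(sigmas, radii):
        lattice = _band_lattice(n_ext, SPACING_FACTOR * sig)
        d = np.hypot(lattice[:, 0] - center, lattice[:, 1] - center)
        sel = (d >= r_in) & (d < r_out)
        pts = np.rint(lattice[sel]).astype(np.intp)
        centers_list.append(pts)
        band_slices.append(slice(start, start + len(pts)))
        start += len(pts)
        r_in = r_out
    centers = np.concatenate(centers_list, axis=0)
    if len(centers) == 0:
        raise ValueError("basis is empty; decrease sigma0")
    return GaussianBasisSpec(
        n_ext=n_ext,
        centers=centers,
        sigmas=np.asarray(sigmas),
        band_slices=band_slices,
        band_radii=np.asarray(radii),
    )


def synthesize(basis: GaussianBasisSpec, coeffs: np.ndarray) -> np.ndarray:
    """Operator G: accumulate each coefficient's truncated blob (N2^2 image).

    Per band, coefficients are scattered at their centers and the result is
    convolved with the separable truncated kernel.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != (basis.n_coeffs,):
        raise ValueError("coefficient vector length does not match the basis")
    n = basis.n_ext
    out = np.zeros((n, n), dtype=np.float64)
    for b in range(basis.n_bands):
        cb = coeffs[basis.band_slices[b]]
        if cb.size == 0:
            continue
        pts = basis.band_centers(b)
        img = np.zeros((n, n), dtype=np.float64)
        np.add.at(img, (pts[:, 0], pts[:, 1]), cb)
        img = scipy.ndimage.convolve1d(
            img, basis.kernel(b), axis=0, mode="constant", cval=0.0
        )
        img = scipy.ndimage.convolve1d(
            img, basis.profile(b), axis=1, mode="constant", cval=0.0
        )
        out += img
    return out


def analyze(basis: GaussianBasisSpec, image: np.ndarray) -> np.ndarray:
    """Operator G^T: convolve with each band's kernel and sample at centers."""
    image = np.asarray(image, dtype=np.float64)
    if image.shape != (basis.n_ext, basis.n_ext):
        raise ValueError("image side does not match the basis support")
    coeffs = np.empty(basis.n_coeffs, dtype=np.float64)
    for b in range(basis.n_bands):
        sl = basis.band_slices[b]
        if sl.stop == sl.start:
            continue
        tmp = scipy.ndimage.convolve1d(
            image, basis.kernel(b), axis=0, mode="constant", cval=0.0
        )
        tmp = scipy.ndimage.convolve1d(
            tmp, basis.profile(b), axis=1, mode="constant", cval=0.0
        )
        pts = basis.band_centers(b)
        coeffs[sl] = tmp[pts[:, 0], pts[:, 1]]
    return coeffs


def zone_matrix(basis: GaussianBasisSpec, zone, geom) -> scipy.sparse.csr_matrix:
    """Sparse matrix sampling ``G c`` at the known-zone pixels (shape N_Omega x N_g).

    Row p, column i holds the value of blob i at known-zone pixel p, i.e.
    exactly the value :func:`synthesize` would place there.  Zone pixels are
    given in the N^2 ROI frame and mapped into the extended support.
    """
    off = (geom.n_ext - geom.n_roi) // 2
    zr = zone.rows + off
    zc = zone.cols + off
    if zr.min() < 0 or zr.max() >= geom.n_ext:
        raise ValueError("known zone falls outside the extended support")
    n_zone = zr.size
    rows_acc, cols_acc, vals_acc = [], [], []
    for b in range(basis.n_bands):
        sl = basis.band_slices[b]
        pts = basis.band_centers(b)
        if len(pts) == 0:
            continue
        k = basis.kernel(b)
        kp = basis.profile(b)
        half = (len(k) - 1) // 2
        # dr[p, i], dc[p, i]: offsets from blob center to zone pixel
        dr = zr[:, None] - pts[None, :, 0]
        dc = zc[:, None] - pts[None, :, 1]
        inside = (np.abs(dr) <= half) & (np.abs(dc) <= half)
        p_idx, i_idx = np.nonzero(inside)
        vals = k[dr[p_idx, i_idx] + half] * kp[dc[p_idx, i_idx] + half]
        rows_acc.append(p_idx)
        cols_acc.append(i_idx + sl.start)
        vals_acc.append(vals)
    if rows_acc:
        rows = np.concatenate(rows_acc)
        cols = np.concatenate(cols_acc)
        vals = np.concatenate(vals_acc)
    else:  # pragma: no cover - empty basis is rejected earlier
        rows = cols = vals = np.array([])
    return scipy.sparse.csr_matrix(
        (vals, (rows, cols)), shape=(n_zone, basis.n_coeffs)
    )


def restrict_to_known_zone(basis: GaussianBasisSpec, coeffs: np.ndarray, zone, geom) -> np.ndarray:
    """Values of ``G c`` on the known-zone pixels, ``(G c)|_Omega``."""
    return zone_matrix(basis, zone, geom) @ np.asarray(coeffs, dtype=np.float64)
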