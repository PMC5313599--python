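"""Sparse LUT point-projector and the merged forward/adjoint operator.

Because the correction term is a lattice of isolated blobs, projecting it
does not need a general-purpose projector: each blob center projects, at each
angle, onto (at most) one detector position.  The projection of all centers
is therefore precomputed once into a look-up table stored as a sparse matrix
in CSR form — row-start positions ``pos`` into the index array ``j`` of
coefficient indices, with geometric weights ``w`` — together with its
transpose (``pos2``/``j2``/``w2``, the CSC view) for the backprojector.
Applying the point-projector is then a single sparse matrix-vector product.

The blob footprint is applied afterwards as a 1-D Gaussian convolution of
each sinogram row: projecting a Gaussian tiling and convolving the rows is
equivalent to convolving the image first and projecting, because the
Gaussian is rotationally invariant and separable.  The merged operator

    A c = C . conv_rows . S c        (per band, bands summed)

with C the detector crop, realizes the projection of the synthesized
correction image; its adjoint zero-extends the rows, convolves with the same
(symmetric) kernels and applies the transposed LUT.  Forward and adjoint are
exact algebraic transposes, which is what conjugate gradient requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.sparse

from .blobs import GaussianBasisSpec
from .projection import crop_sinogram, extend_sinogram

__all__ = [
    "SparsePointProjector",
    "build_lut",
    "point_project",
    "point_backproject",
    "CorrectionOperator",
]


@dataclass
class SparsePointProjector:
    """CSR/CSC triples of the point-projection matrix for one set of centers."""

    pos: np.ndarray  # (n_sino + 1,) row starts into j/w
    j: np.ndarray  # coefficient indices
    w: np.ndarray  # geometric weights
    pos2: np.ndarray  # (n_coeffs + 1,) row starts of the transpose
    j2: np.ndarray  # sinogram indices
    w2: np.ndarray
    n_sino: int
    n_coeffs: int
    n_angles: int
    width: int
    _csr: scipy.sparse.csr_matrix = field(default=None, repr=False)  # type: ignore[assignment]
    _csc: scipy.sparse.csr_matrix = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def nnz(self) -> int:
        return int(self.j.size)

    def as_csr(self) -> scipy.sparse.csr_matrix:
        """The (n_sino x n_coeffs) matrix wrapping the CSR triple (zero-copy)."""
        if self._csr is None:
            self._csr = scipy.sparse.csr_matrix(
                (self.w, self.j, self.pos), shape=(self.n_sino, self.n_coeffs)
            )
        return self._csr

    def as_csr_transpose(self) -> scipy.sparse.csr_matrix:
        """The (n_coeffs x n_sino) transpose wrapping the CSC triple."""
        if self._csc is None:
            self._csc = scipy.sparse.csr_matrix(
                (self.w2, self.j2, self.pos2), shape=(self.n_coeffs, self.n_sino)
            )
        return self._csc


def build_lut(
    centers: np.ndarray,
    angles: np.ndarray,
    width: int,
    center: float | None = None,
    mode: str = "linear",
) -> SparsePointProjector:
    """Project every center at every angle and assemble the CSR/CSC LUTs.

    Each center (row y, col x) hits the continuous detector coordinate
    ``t = (x - cc) cos(theta) + (y - cc) sin(theta) + center`` at each angle.
    ``mode="linear"`` splats onto the two neighboring bins with weights
    ``1 - frac`` and ``frac`` (an exact ``frac = 0`` keeps a single
    weight-one entry); ``mode="nearest"`` records one bin with weight one.
    Hits outside the detector are dropped.  Entries are sorted by
    (sinogram index, coefficient index) for the CSR triple and by
    (coefficient index, sinogram index) for its transpose, so the structure
    is deterministic.
    """
    centers = np.asarray(centers, dtype=np.float64)
    angles = np.asarray(angles, dtype=np.float64)
    n_coeffs = centers.shape[0]
    n_angles = angles.size
    n_sino = n_angles * width
    cc = (width - 1) / 2.0
    if center is None:
        center = cc
    y = centers[:, 0]
    x = centers[:, 1]
    if np.any((x < 0) | (x >= width) | (y < 0) | (y >= width)):
        raise ValueError("blob centers must lie inside the extended support")
    ct = np.cos(angles)[:, None]
    st = np.sin(angles)[:, None]
    t = (x[None, :] - cc) * ct + (y[None, :] - cc) * st + center  # (Np, Ng)
    coeff_idx = np.broadcast_to(np.arange(n_coeffs, dtype=np.intp), t.shape)
    angle_idx = np.broadcast_to(np.arange(n_angles, dtype=np.intp)[:, None], t.shape)

    if mode == "nearest":
        b = np.rint(t).astype(np.intp)
        keep = (b >= 0) & (b < width)
        k_idx = angle_idx[keep] * width + b[keep]
        i_idx = coeff_idx[keep]
        wts = np.ones(k_idx.size, dtype=np.float64)
    elif mode == "linear":
        b0 = np.floor(t).astype(np.intp)
        frac = t - b0
        keep0 = (b0 >= 0) & (b0 < width)
        keep1 = (b0 + 1 >= 0) & (b0 + 1 < width) & (frac > 0)
        k_idx = np.concatenate(
            (angle_idx[keep0] * width + b0[keep0], angle_idx[keep1] * width + b0[keep1] + 1)
        )
        i_idx = np.concatenate((coeff_idx[keep0], coeff_idx[keep1]))
        wts = np.concatenate((1.0 - frac[keep0], frac[keep1]))
    else:
        raise ValueError("mode must be 'linear' or 'nearest'")

    # CSR: sort by (sinogram index, coefficient index)
    order = np.lexsort((i_idx, k_idx))
    j = i_idx[order]
    w = wts[order]
    pos = np.zeros(n_sino + 1, dtype=np.intp)
    np.cumsum(np.bincount(k_idx[order], minlength=n_sino), out=pos[1:])

    # CSC (transpose): sort by (coefficient index, sinogram index)
    order2 = np.lexsort((k_idx, i_idx))
    j2 = k_idx[order2]
    w2 = wts[order2]
    pos2 = np.zeros(n_coeffs + 1, dtype=np.intp)
    np.cumsum(np.bincount(i_idx[order2], minlength=n_coeffs), out=pos2[1:])

    return SparsePointProjector(
        pos=pos,
        j=j,
        w=w,
        pos2=pos2,
        j2=j2,
        w2=w2,
        n_sino=n_sino,
        n_coeffs=n_coeffs,
        n_angles=n_angles,
        width=width,
    )


def point_project(P: SparsePointProjector, coeffs: np.ndarray) -> np.ndarray:
    """Sparse CSR matvec: sinogram of the isolated points, shape (Np, width)."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.shape != (P.n_coeffs,):
        raise ValueError("coefficient vector length does not match the LUT")
    return (P.as_csr() @ coeffs).reshape(P.n_angles, P.width)


def point_backproject(P: SparsePointProjector, sino: np.ndarray) -> np.ndarray:
    """Exact transpose of :func:`point_project` via the CSC triple."""
    sino = np.asarray(sino, dtype=np.float64)
    if sino.size != P.n_sino:
        raise ValueError("sinogram size does not match the LUT")
    return P.as_csr_transpose() @ sino.ravel()


def _centered_kernel_fft(kernel: np.ndarray, nfft: int) -> np.ndarray:
    """rfft of the symmetric kernel placed circularly with its center at 0.

    The result is real (even symmetry), so per-band filtering keeps rows real
    and the circular convolution operator is self-adjoint.
    """
    half = (len(kernel) - 1) // 2
    buf = np.zeros(nfft, dtype=np.float64)
    buf[: half + 1] = kernel[half:]
    if half > 0:
        buf[-half:] = kernel[:half]
    return np.real(scipy.fft.rfft(buf))


class CorrectionOperator:
    """The bundled forward model ``A = C . P-tilde . G`` restricted to blobs.

    Per band: sparse point-projection of the band's coefficients, 1-D
    convolution of each sinogram row with the band's Gaussian kernel (shared
    with the image-domain synthesis), frequency-domain accumulation over
    bands, and a final crop to the acquired detector width.
    """

    def __init__(self, basis: GaussianBasisSpec, geom, mode: str = "linear"):
        self.basis = basis
        self.geom = geom
        self.width = geom.n_ext
        self.n_roi = geom.n_roi
        self.n_angles = geom.n_angles
        self.projectors = [
            build_lut(basis.band_centers(b), geom.angles, self.width, geom.center, mode)
            for b in range(basis.n_bands)
        ]
        max_len = max(len(basis.profile(b)) for b in range(basis.n_bands))
        self.nfft = scipy.fft.next_fast_len(self.width + max_len - 1, real=True)
        # row-convolution kernel: the discrete blob's own 1-D projection —
        # the unnormalized profile scaled by the discrete mass of the
        # normalized factor, so axis-aligned projections of a synthesized
        # blob are matched exactly
        self.kernel_ffts = [
            _centered_kernel_fft(
                basis.profile(b) * basis.kernel(b).sum(), self.nfft
            )
            for b in range(basis.n_bands)
        ]

    @property
    def n_coeffs(self) -> int:
        return self.basis.n_coeffs

    def forward(self, coeffs: np.ndarray) -> np.ndarray:
        """Sinogram (Np x N) of the synthesized correction image."""
        coeffs = np.asarray(coeffs, dtype=np.float64)
        if coeffs.shape != (self.n_coeffs,):
            raise ValueError("coefficient vector length does not match the basis")
        spec = np.zeros((self.n_angles, self.nfft // 2 + 1), dtype=np.complex128)
        for b, P in enumerate(self.projectors):
            sl = self.basis.band_slices[b]
            if sl.stop == sl.start:
                continue
            pts = point_project(P, coeffs[sl])
            spec += scipy.fft.rfft(pts, self.nfft, axis=1) * self.kernel_ffts[b]
        ext = scipy.fft.irfft(spec, self.nfft, axis=1)[:, : self.width]
        return crop_sinogram(ext, self.n_roi)

    def adjoint(self, residual: np.ndarray) -> np.ndarray:
        """Exact transpose of :func:`forward`."""
        residual = np.asarray(residual, dtype=np.float64)
        if residual.shape != (self.n_angles, self.n_roi):
            raise ValueError("residual shape does not match the acquisition")
        ext = extend_sinogram(residual, self.width)
        spec = scipy.fft.rfft(ext, self.nfft, axis=1)
        coeffs = np.empty(self.n_coeffs, dtype=np.float64)
        for b, P in enumerate(self.projectors):
            sl = self.basis.band_slices[b]
            if sl.stop == sl.start:
                continue
            rows = scipy.fft.irfft(spec * self.kernel_ffts[b], self.nfft, axis=1)
            coeffs[sl] = point_backproject(P, rows[:, : self.width])
        return coeffs
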