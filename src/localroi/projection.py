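"""Dense parallel-beam projector/backprojector, cropping, padding and FBP.

The projector uses Joseph-style ray sampling: each ray is stepped along its
dominant axis, linearly interpolating the image along the other axis, with a
path-length weight ``1/max(|cos|, |sin|)``.  The backprojector scatters with
the identical weights, so the pair is an exact algebraic adjoint — the
property the conjugate-gradient solver relies on.

A pixel at (row r, col c) of an n-wide image projects, at angle theta, to the
continuous detector coordinate

    t = (c - cc) cos(theta) + (r - cc) sin(theta) + center

with cc = (n - 1)/2 and center = (width - 1)/2 by default.
"""

from __future__ import annotations

import numpy as np
import scipy.fft

try:  # optional JIT acceleration of the ray loops
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is normally available
    _HAVE_NUMBA = False

__all__ = [
    "project",
    "backproject",
    "pad_sinogram",
    "crop_sinogram",
    "crop_image",
    "embed_image",
    "extend_sinogram",
    "padded_fbp",
    "ramp_filter_sinogram",
]


def _angle_setup(side: int, theta: float, center: float, width: int):
    """Stepping-axis geometry for one angle.

    Returns (transposed, pos) where ``pos[s, b]`` is the continuous gather
    coordinate in the non-dominant axis for step index ``s`` and detector bin
    ``b``, plus the path-length weight.  ``transposed`` means the image must
    be addressed as ``img.T`` (column-dominant stepping).
    """
    ct, st = np.cos(theta), np.sin(theta)
    cc = (side - 1) / 2.0
    bins = np.arange(width, dtype=np.float64)
    steps = np.arange(side, dtype=np.float64)
    if abs(ct) >= abs(st):
        u, v = st, ct
        transposed = False
    else:
        u, v = ct, st
        transposed = True
    pos = (bins[None, :] - center - (steps[:, None] - cc) * u) / v + cc
    weight = 1.0 / abs(v)
    return transposed, pos, weight


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=False)
    def _project_kernel(img, imgT, angles, center, sino):  # pragma: no cover
        side = img.shape[0]
        width = sino.shape[1]
        cc = (side - 1) / 2.0
        for a in range(angles.size):
            ct = np.cos(angles[a])
            st = np.sin(angles[a])
            if abs(ct) >= abs(st):
                u, v = st, ct
                A = img
            else:
                u, v = ct, st
                A = imgT
            w = 1.0 / abs(v)
            dpos = -u / v
            for b in range(width):
                pos = cc + (b - center + cc * u) / v
                acc = 0.0
                for s in range(side):
                    i0 = int(np.floor(pos))
                    f = pos - i0
                    if 0 <= i0 < side:
                        acc += (1.0 - f) * A[s, i0]
                    i1 = i0 + 1
                    if 0 <= i1 < side:
                        acc += f * A[s, i1]
                    pos += dpos
                sino[a, b] = w * acc

    @numba.njit(cache=True, fastmath=False)
    def _backproject_kernel(sino, angles, center, out, outT):  # pragma: no cover
        side = out.shape[0]
        width = sino.shape[1]
        cc = (side - 1) / 2.0
        for a in range(angles.size):
            ct = np.cos(angles[a])
            st = np.sin(angles[a])
            if abs(ct) >= abs(st):
                u, v = st, ct
                transposed = False
            else:
                u, v = ct, st
                transposed = True
            w = 1.0 / abs(v)
            dpos = -u / v
            for b in range(width):
                val = w * sino[a, b]
                if val == 0.0:
                    continue
                pos = cc + (b - center + cc * u) / v
                if transposed:
                    for s in range(side):
                        i0 = int(np.floor(pos))
                        f = pos - i0
                        if 0 <= i0 < side:
                            outT[s, i0] += (1.0 - f) * val
                        i1 = i0 + 1
                        if 0 <= i1 < side:
                            outT[s, i1] += f * val
                        pos += dpos
                else:
                    for s in range(side):
                        i0 = int(np.floor(pos))
                        f = pos - i0
                        if 0 <= i0 < side:
                            out[s, i0] += (1.0 - f) * val
                        i1 = i0 + 1
                        if 0 <= i1 < side:
                            out[s, i1] += f * val
                        pos += dpos


def project(image: np.ndarray, angles: np.ndarray, center: float | None = None) -> np.ndarray:
    """Parallel-beam line integrals of a square image.

    The detector has the same width as the image.  Linear in the image.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("image must be square")
    side = image.shape[0]
    width = side
    if center is None:
        center = (width - 1) / 2.0
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    sino = np.empty((angles.size, width), dtype=np.float64)
    imgT = np.ascontiguousarray(image.T)
    if _HAVE_NUMBA:
        _project_kernel(np.ascontiguousarray(image), imgT, angles, float(center), sino)
        return sino
    for a, theta in enumerate(angles):
        transposed, pos, w = _angle_setup(side, theta, center, width)
        A = imgT if transposed else image
        i0 = np.floor(pos).astype(np.intp)
        f = pos - i0
        v0 = (i0 >= 0) & (i0 < side)
        v1 = (i0 >= -1) & (i0 < side - 1)
        i0c = np.clip(i0, 0, side - 1)
        i1c = np.clip(i0 + 1, 0, side - 1)
        g0 = np.take_along_axis(A, i0c, axis=1)
        g1 = np.take_along_axis(A, i1c, axis=1)
        vals = np.where(v0, (1.0 - f) * g0, 0.0) + np.where(v1, f * g1, 0.0)
        sino[a] = w * vals.sum(axis=0)
    return sino


def backproject(
    sino: np.ndarray, side: int, angles: np.ndarray, center: float | None = None
) -> np.ndarray:
    """Exact algebraic adjoint of :func:`project` (unfiltered)."""
    sino = np.asarray(sino, dtype=np.float64)
    angles = np.atleast_1d(np.asarray(angles, dtype=np.float64))
    if sino.ndim != 2 or sino.shape[0] != angles.size:
        raise ValueError("sinogram shape does not match the angle list")
    width = sino.shape[1]
    if width != side:
        raise ValueError("detector width must equal the image side")
    if center is None:
        center = (width - 1) / 2.0
    out = np.zeros((side, side), dtype=np.float64)
    outT = np.zeros((side, side), dtype=np.float64)
    if _HAVE_NUMBA:
        _backproject_kernel(
            np.ascontiguousarray(sino), angles, float(center), out, outT
        )
        return out + outT.T
    steps = np.arange(side, dtype=np.intp)
    for a, theta in enumerate(angles):
        transposed, pos, w = _angle_setup(side, theta, center, width)
        i0 = np.floor(pos).astype(np.intp)
        f = pos - i0
        v0 = (i0 >= 0) & (i0 < side)
        v1 = (i0 >= -1) & (i0 < side - 1)
        i0c = np.clip(i0, 0, side - 1)
        i1c = np.clip(i0 + 1, 0, side - 1)
        row = w * sino[a]
        w0 = np.where(v0, (1.0 - f), 0.0) * row[None, :]
        w1 = np.where(v1, f, 0.0) * row[None, :]
        base = steps[:, None] * side
        idx = np.concatenate(((base + i0c).ravel(), (base + i1c).ravel()))
        wts = np.concatenate((w0.ravel(), w1.ravel()))
        acc = np.bincount(idx, weights=wts, minlength=side * side)
        tgt = outT if transposed else out
        tgt += acc.reshape(side, side)
    return out + outT.T


def pad_sinogram(sino: np.ndarray, new_width: int) -> np.ndarray:
    """Widen each row symmetrically by replicating its edge values."""
    sino = np.asarray(sino)
    width = sino.shape[1]
    if new_width < width:
        raise ValueError("new_width must be >= current width")
    left = (new_width - width) // 2
    right = new_width - width - left
    return np.pad(sino, ((0, 0), (left, right)), mode="edge")


def crop_sinogram(sino: np.ndarray, n_roi: int) -> np.ndarray:
    """Keep the ``n_roi`` central columns of every row (operator C)."""
    sino = np.asarray(sino)
    width = sino.shape[1]
    if n_roi > width:
        raise ValueError("cannot crop to a width larger than the sinogram")
    start = (width - n_roi) // 2
    return sino[:, start : start + n_roi]


def extend_sinogram(sino: np.ndarray, new_width: int) -> np.ndarray:
    """Zero-extend each row symmetrically; the adjoint of :func:`crop_sinogram`."""
    sino = np.asarray(sino)
    width = sino.shape[1]
    if new_width < width:
        raise ValueError("new_width must be >= current width")
    left = (new_width - width) // 2
    out = np.zeros((sino.shape[0], new_width), dtype=sino.dtype)
    out[:, left : left + width] = sino
    return out


def crop_image(image: np.ndarray, n_roi: int) -> np.ndarray:
    """Central n_roi x n_roi square of an image (operator C-tilde)."""
    image = np.asarray(image)
    side = image.shape[0]
    if n_roi > side:
        raise ValueError("cannot crop to a side larger than the image")
    start = (side - n_roi) // 2
    return image[start : start + n_roi, start : start + n_roi]


def embed_image(image: np.ndarray, new_side: int) -> np.ndarray:
    """Zero-pad an image symmetrically to ``new_side``; adjoint of :func:`crop_image`."""
    image = np.asarray(image)
    side = image.shape[0]
    if new_side < side:
        raise ValueError("new_side must be >= current side")
    start = (new_side - side) // 2
    out = np.zeros((new_side, new_side), dtype=image.dtype)
    out[start : start + side, start : start + side] = image
    return out


def _ramp_kernel(nfft: int) -> np.ndarray:
    """Discrete Ram-Lak filter (frequency response), Kak & Slaney construction."""
    n = np.concatenate(
        (np.arange(1, nfft // 2 + 1, 2), np.arange(nfft // 2 - 1, 0, -2))
    )
    f = np.zeros(nfft)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * n) ** 2
    return 2.0 * np.real(scipy.fft.fft(f))


def ramp_filter_sinogram(sino: np.ndarray) -> np.ndarray:
    """Apply the ramp (Ram-Lak) filter to every sinogram row.

    FFTs are zero-padded to the next power of two >= 2x the row width and
    carried out in float64.
    """
    sino = np.asarray(sino, dtype=np.float64)
    width = sino.shape[1]
    nfft = max(64, int(2 ** np.ceil(np.log2(2 * width))))
    filt = _ramp_kernel(nfft)
    spec = scipy.fft.fft(sino, nfft, axis=1) * filt[None, :]
    return np.real(scipy.fft.ifft(spec, axis=1))[:, :width]


def padded_fbp(
    sino_truncated: np.ndarray,
    geom,
    pad_width: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Edge-padded filtered backprojection of a truncated sinogram.

    Each row is replicated out to the extended width N2, ramp-filtered, and
    backprojected on the N2^2 grid with the normalization ``pi / (2 Np)``.

    Returns
    -------
    x0 : ndarray
        The N^2 ROI crop of the reconstruction.
    x0_ext : ndarray
        The N2^2 image obtained by re-embedding ``x0`` with zeros outside
        the ROI support (the extension used by the correction model).
    """
    sino_truncated = np.asarray(sino_truncated, dtype=np.float64)
    if sino_truncated.shape[1] != geom.n_roi:
        raise ValueError("sinogram width must equal geom.n_roi")
    if pad_width is None:
        pad_width = geom.n_ext
    padded = pad_sinogram(sino_truncated, pad_width)
    filtered = ramp_filter_sinogram(padded)
    recon = backproject(filtered, pad_width, geom.angles)
    recon *= np.pi / (2.0 * geom.n_angles)
    x0 = crop_image(recon, geom.n_roi)
    x0_ext = embed_image(x0, geom.n_ext)
    return x0, x0_ext
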