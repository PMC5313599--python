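"""Synthetic phantoms and local-tomography test setups.

Everything downstream (projection, blob fitting, solvers, benchmarks) is
exercised on simulated data produced here: a Shepp-Logan head phantom, a
truncated ("interior") sinogram obtained by keeping only the central detector
columns of a full simulation, and a known subregion whose true attenuation
values serve as the prior for the correction solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocalGeometry",
    "KnownZone",
    "LocalSetup",
    "make_shepp_logan",
    "make_local_setup",
    "SHEPP_LOGAN_ELLIPSES",
]


# Ellipse table of the Shepp-Logan head phantom.
# Columns: intensity, x half-axis, y half-axis, x center, y center, angle (deg),
# all in the unit square [-1, 1]^2.  "classical" uses the original low-contrast
# intensities; "modified" is the common high-contrast variant used for display.
_SL_GEOMETRY = np.array(
    [
        # a      b      x0     y0     phi
        [0.6900, 0.9200, 0.00, 0.0000, 0.0],
        [0.6624, 0.8740, 0.00, -0.0184, 0.0],
        [0.1100, 0.3100, 0.22, 0.0000, -18.0],
        [0.1600, 0.4100, -0.22, 0.0000, 18.0],
        [0.2100, 0.2500, 0.00, 0.3500, 0.0],
        [0.0460, 0.0460, 0.00, 0.1000, 0.0],
        [0.0460, 0.0460, 0.00, -0.1000, 0.0],
        [0.0460, 0.0230, -0.08, -0.6050, 0.0],
        [0.0230, 0.0230, 0.00, -0.6060, 0.0],
        [0.0230, 0.0460, 0.06, -0.6050, 0.0],
    ]
)
_SL_INTENSITY = {
    "classical": np.array([1.0, -0.98, -0.02, -0.02, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01]),
    "modified": np.array([1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]),
}

#: (intensity, a, b, x0, y0, phi_deg) rows of the default (classical) phantom.
SHEPP_LOGAN_ELLIPSES = np.hstack(
    [_SL_INTENSITY["classical"][:, None], _SL_GEOMETRY]
)


@dataclass
class LocalGeometry:
    """Geometry of a parallel-beam interior-tomography acquisition.

    Parameters
    ----------
    n_roi : int
        Detector width N; the reconstructed region of interest is the disk
        inscribed in the central ``n_roi``-wide square.
    n_ext : int
        Width N2 of the extended reconstruction support used to model the
        (unmeasured) exterior of the ROI.
    n_angles : int
        Number of projection angles Np.
    n_full : int or None
        Width N0 of the true object support; known only for simulations.
    angles : ndarray
        Projection angles in radians, evenly spaced over ``[0, pi)``.
    center : float
        Continuous detector coordinate of the rotation axis on the extended
        detector, ``(n_ext - 1) / 2``.
    """

    n_roi: int
    n_ext: int
    n_angles: int
    n_full: int | None = None
    angles: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    center: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.n_ext < self.n_roi:
            raise ValueError("n_ext must be >= n_roi")
        if self.angles is None:
            self.angles = np.arange(self.n_angles) * np.pi / self.n_angles
        self.angles = np.asarray(self.angles, dtype=np.float64)
        if self.center is None:
            self.center = (self.n_ext - 1) / 2.0
        if not (0 <= self.center < self.n_ext):
            raise ValueError("rotation center must lie on the extended detector")


@dataclass
class KnownZone:
    """A subregion of the ROI with a priori known attenuation values.

    ``rows``/``cols`` index pixels in the N^2 ROI frame; ``values`` are the
    true attenuation values on those pixels, and ``weight`` is the penalty
    weight (beta) of the known-zone data term.
    """

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray
    weight: float = 1.0

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.rows.size == 0:
            raise ValueError("known zone must contain at least one pixel")
        if not (self.rows.size == self.cols.size == self.values.size):
            raise ValueError("rows, cols and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("known-zone values must be finite")
        if self.weight < 0:
            raise ValueError("known-zone weight must be nonnegative")

    @property
    def size(self) -> int:
        return int(self.rows.size)


@dataclass
class LocalSetup:
    """A complete simulated interior-tomography problem instance."""

    geom: LocalGeometry
    zone: KnownZone
    sinogram: "np.ndarray"  # truncated, (n_angles, n_roi)
    truth_roi: np.ndarray  # ground-truth central N^2 crop
    phantom: np.ndarray  # full N0^2 ground truth
    full_sinogram: np.ndarray  # untruncated, (n_angles, n_full)


def make_shepp_logan(
    side: int, variant: str = "modified", supersample: int = 1
) -> np.ndarray:
    """Sample the 10-ellipse Shepp-Logan head phantom on a ``side**2`` grid.

    The phantom lives in the unit square; a pixel's value is the sum of the
    intensities of all ellipses containing its center.  Deterministic.

    ``variant="modified"`` (default) uses the common high-contrast
    intensities; ``"classical"`` the original low-contrast ones.  With
    ``supersample = k > 1`` each pixel averages a k x k subgrid, giving an
    anti-aliased phantom whose edges are band-limited at the pixel scale
    (the appropriate ground truth when comparing against filtered
    backprojection, which cannot represent sub-pixel jagged edges).
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    if supersample > 1:
        big = make_shepp_logan(side * supersample, variant=variant)
        return big.reshape(side, supersample, side, supersample).mean(axis=(1, 3))
    try:
        intens = _SL_INTENSITY[variant]
    except KeyError:
        raise ValueError(f"unknown variant {variant!r}") from None
    cc = (side - 1) / 2.0
    scale = side / 2.0
    c = np.arange(side)
    x = (c - cc) / scale
    y = (cc - c) / scale  # row index grows downwards, y grows upwards
    X, Y = np.meshgrid(x, y[:, None].ravel(), indexing="xy")
    img = np.zeros((side, side), dtype=np.float64)
    for amp, (a, b, x0, y0, phi) in zip(intens, _SL_GEOMETRY):
        th = np.deg2rad(phi)
        ct, st = np.cos(th), np.sin(th)
        xr = (X - x0) * ct + (Y - y0) * st
        yr = -(X - x0) * st + (Y - y0) * ct
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += amp
    return img


def disk_mask(side: int, radius: float, center: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean mask of pixel centers strictly inside a disk."""
    if center is None:
        center = ((side - 1) / 2.0, (side - 1) / 2.0)
    r = np.arange(side)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2


def make_local_setup(
    phantom: np.ndarray,
    roi_diameter: int,
    n_angles: int,
    known_radius: float | None = None,
    known_center: tuple[float, float] | None = None,
    n_ext: int | None = None,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> LocalSetup:
    """Simulate a truncated acquisition of ``phantom`` and its known zone.

    The full sinogram is computed over ``n_angles`` angles in ``[0, pi)`` and
    truncated to the ``roi_diameter`` central detector columns.  The known
    zone is a disk (default: centered in the ROI, radius ``roi_diameter/10``)
    whose values are read off the phantom.

    Parameters
    ----------
    noise_sigma : float
        Standard deviation of optional additive Gaussian noise on the
        sinogram (0 disables it; default).
    """
    from .projection import crop_image, crop_sinogram, project

    phantom = np.asarray(phantom, dtype=np.float64)
    n_full = phantom.shape[0]
    if phantom.ndim != 2 or phantom.shape[0] != phantom.shape[1]:
        raise ValueError("phantom must be a square image")
    if roi_diameter > n_full:
        raise ValueError("roi_diameter cannot exceed the phantom side")
    if known_radius is None:
        known_radius = roi_diameter / 10.0
    if known_radius >= roi_diameter / 2.0:
        raise ValueError("known disk must lie strictly inside the ROI")
    if n_ext is None:
        n_ext = int(round(2.1 * roi_diameter))
        n_ext = max(n_ext, roi_diameter)
    # keep the truncation symmetric: pad/crop assume matching parity
    if (n_ext - roi_diameter) % 2:
        n_ext += 1
    if (n_full - roi_diameter) % 2:
        raise ValueError(
            "phantom side and roi_diameter must have equal parity "
            "(symmetric truncation)"
        )

    geom = LocalGeometry(
        n_roi=roi_diameter, n_ext=n_ext, n_angles=n_angles, n_full=n_full
    )

    full_sino = project(phantom, geom.angles)
    if noise_sigma > 0:
        rng = np.random.default_rng() if rng is None else rng
        full_sino = full_sino + rng.normal(0.0, noise_sigma, full_sino.shape)
    sino = crop_sinogram(full_sino, roi_diameter)

    truth_roi = crop_image(phantom, roi_diameter)

    roi_c = (roi_diameter - 1) / 2.0
    if known_center is None:
        known_center = (roi_c, roi_c)
    # the known disk must stay inside the ROI disk
    dist = np.hypot(known_center[0] - roi_c, known_center[1] - roi_c)
    if dist + known_radius >= roi_diameter / 2.0:
        raise ValueError("known disk must lie strictly inside the ROI disk")
    mask = disk_mask(roi_diameter, known_radius, known_center)
    rows, cols = np.nonzero(mask)
    zone = KnownZone(rows=rows, cols=cols, values=truth_roi[rows, cols])

    return LocalSetup(
        geom=geom,
        zone=zone,
        sinogram=sino,
        truth_roi=truth_roi,
        phantom=phantom,
        full_sinogram=full_sino,
    )
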