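"""TIFF and HDF5 readers/writers for images, sinograms, setups and LUTs."""

from __future__ import annotations

import h5py
import numpy as np
import tifffile

from .blobs import GaussianBasisSpec
from .phantoms import KnownZone, LocalGeometry, LocalSetup
from .pointproj import SparsePointProjector

__all__ = [
    "write_tiff",
    "read_tiff",
    "write_image_h5",
    "write_sinogram_h5",
    "read_sinogram_h5",
    "write_setup_h5",
    "read_setup_h5",
    "write_basis_h5",
    "read_basis_h5",
    "write_lut_h5",
    "read_lut_h5",
]

LUT_FORMAT_VERSION = 1


def write_tiff(path, data: np.ndarray) -> None:
    """Single-page float32 TIFF."""
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_image_h5(path, data: np.ndarray, name: str = "data") -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset(name, data=np.asarray(data, dtype=np.float32))


def write_sinogram_h5(path, sino: np.ndarray, angles: np.ndarray, center: float, n_roi: int) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=np.asarray(sino, dtype=np.float32))
        ds.attrs["angles"] = np.asarray(angles)
        ds.attrs["center"] = float(center)
        ds.attrs["n_roi"] = int(n_roi)


def read_sinogram_h5(path):
    with h5py.File(path, "r") as f:
        ds = f["data"]
        return (
            np.asarray(ds, dtype=np.float64),
            np.asarray(ds.attrs["angles"]),
            float(ds.attrs["center"]),
            int(ds.attrs["n_roi"]),
        )


def write_setup_h5(path, setup: LocalSetup) -> None:
    """Persist a simulated problem instance (sinogram, geometry, zone, truth)."""
    with h5py.File(path, "w") as f:
        g = setup.geom
        ds = f.create_dataset("sinogram", data=np.asarray(setup.sinogram, dtype=np.float32))
        ds.attrs["angles"] = g.angles
        ds.attrs["center"] = g.center
        ds.attrs["n_roi"] = g.n_roi
        ds.attrs["n_ext"] = g.n_ext
        ds.attrs["n_full"] = -1 if g.n_full is None else g.n_full
        f.create_dataset("truth_roi", data=np.asarray(setup.truth_roi, dtype=np.float32))
        z = f.create_group("known_zone")
        z.create_dataset("rows", data=setup.zone.rows)
        z.create_dataset("cols", data=setup.zone.cols)
        z.create_dataset("values", data=setup.zone.values)
        z.attrs["weight"] = setup.zone.weight


def read_setup_h5(path) -> LocalSetup:
    with h5py.File(path, "r") as f:
        ds = f["sinogram"]
        n_full = int(ds.attrs["n_full"])
        geom = LocalGeometry(
            n_roi=int(ds.attrs["n_roi"]),
            n_ext=int(ds.attrs["n_ext"]),
            n_angles=len(ds.attrs["angles"]),
            n_full=None if n_full < 0 else n_full,
            angles=np.asarray(ds.attrs["angles"]),
            center=float(ds.attrs["center"]),
        )
        z = f["known_zone"]
        zone = KnownZone(
            rows=np.asarray(z["rows"]),
            cols=np.asarray(z["cols"]),
            values=np.asarray(z["values"], dtype=np.float64),
            weight=float(z.attrs["weight"]),
        )
        return LocalSetup(
            geom=geom,
            zone=zone,
            sinogram=np.asarray(ds, dtype=np.float64),
            truth_roi=np.asarray(f["truth_roi"], dtype=np.float64),
            phantom=np.zeros((0, 0)),
            full_sinogram=np.zeros((0, 0)),
        )


def write_basis_h5(path, basis: GaussianBasisSpec) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("centers", data=basis.centers)
        f.create_dataset("sigmas", data=basis.sigmas)
        f.create_dataset(
            "band_starts",
            data=np.asarray([s.start for s in basis.band_slices] + [basis.n_coeffs]),
        )
        f.create_dataset("band_radii", data=basis.band_radii)
        f.attrs["spacing_factor"] = basis.spacing_factor
        f.attrs["n_ext"] = basis.n_ext


def read_basis_h5(path) -> GaussianBasisSpec:
    with h5py.File(path, "r") as f:
        starts = np.asarray(f["band_starts"])
        return GaussianBasisSpec(
            n_ext=int(f.attrs["n_ext"]),
            centers=np.asarray(f["centers"]),
            sigmas=np.asarray(f["sigmas"]),
            band_slices=[
                slice(int(a), int(b)) for a, b in zip(starts[:-1], starts[1:])
            ],
            band_radii=np.asarray(f["band_radii"]),
            spacing_factor=float(f.attrs["spacing_factor"]),
        )


def write_lut_h5(path, lut: SparsePointProjector) -> None:
    """Persist the CSR/CSC triples so the LUT can be reused across slices."""
    with h5py.File(path, "w") as f:
        for name in ("pos", "j", "w", "pos2", "j2", "w2"):
            f.create_dataset(name, data=getattr(lut, name))
        f.attrs["n_sino"] = lut.n_sino
        f.attrs["n_coeffs"] = lut.n_coeffs
        f.attrs["n_angles"] = lut.n_angles
        f.attrs["width"] = lut.width
        f.attrs["format_version"] = LUT_FORMAT_VERSION


def read_lut_h5(path) -> SparsePointProjector:
    with h5py.File(path, "r") as f:
        if int(f.attrs["format_version"]) != LUT_FORMAT_VERSION:
            raise ValueError("unsupported LUT format version")
        return SparsePointProjector(
            pos=np.asarray(f["pos"]),
            j=np.asarray(f["j"]),
            w=np.asarray(f["w"]),
            pos2=np.asarray(f["pos2"]),
            j2=np.asarray(f["j2"]),
            w2=np.asarray(f["w2"]),
            n_sino=int(f.attrs["n_sino"]),
            n_coeffs=int(f.attrs["n_coeffs"]),
            n_angles=int(f.attrs["n_angles"]),
            width=int(f.attrs["width"]),
        )
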