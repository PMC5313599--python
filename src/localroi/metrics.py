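"""Evaluation metrics: PSNR over the ROI disk and central line profiles."""

from __future__ import annotations

import numpy as np

from .phantoms import disk_mask

__all__ = ["psnr", "line_profile"]


def psnr(
    x: np.ndarray,
    ref: np.ndarray,
    mask: np.ndarray | None = None,
    peak: float | None = None,
) -> float:
    """Peak signal-to-noise ratio ``10 log10(peak^2 / MSE)`` in dB.

    By default the MSE is taken over the disk inscribed in the image square
    (the reconstructed ROI) and the peak is the maximum of the reference over
    that mask.  Returns ``inf`` when the images agree exactly on the mask.
    """
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if x.shape != ref.shape:
        raise ValueError("images must have equal shapes")
    if mask is None:
        mask = disk_mask(x.shape[0], x.shape[0] / 2.0)
    if not np.any(mask):
        raise ValueError("mask must be nonempty")
    err = x[mask] - ref[mask]
    mse = float(np.mean(err**2))
    if peak is None:
        peak = float(np.max(ref[mask]))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def line_profile(x: np.ndarray, axis: str = "row") -> np.ndarray:
    """Central row or column of an image (index ``side // 2``)."""
    x = np.asarray(x)
    mid = x.shape[0] // 2
    if axis == "row":
        return x[mid, :].copy()
    if axis == "column":
        return x[:, x.shape[1] // 2].copy()
    raise ValueError("axis must be 'row' or 'column'")
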