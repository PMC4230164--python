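"""Spatial smoothing and temporal high-pass filtering."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


def gaussian_smooth(volume: np.ndarray,
                    fwhm_mm: float | tuple[float, float, float],
                    voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    """Separable Gaussian smoothing of a 3-D (or 4-D, last-axis time) map.

    ``sigma_axis = (fwhm / voxel_size) * 1/sqrt(8 ln 2)`` in voxel units;
    reflective boundaries preserve the volume mean. ``fwhm = 0`` on an axis
    leaves that axis untouched.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError(f"fwhm must be >= 0, got {fwhm}")
    if np.all(fwhm == 0):
        return np.asarray(volume, dtype=float).copy()
    sigma_vox = fwhm / np.asarray(voxel_size_mm, dtype=float) * FWHM_TO_SIGMA
    out = np.asarray(volume, dtype=float)
    if out.ndim == 4:
        sigma = tuple(sigma_vox) + (0.0,)
    elif out.ndim == 3:
        sigma = tuple(sigma_vox)
    else:
        raise ValueError("expected a 3-D or 4-D array")
    return ndimage.gaussian_filter(out, sigma=sigma, mode="reflect")


def dct_highpass_basis(n_scans: int, tr_s: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis: all components with period > cutoff_s.

    Columns are the constant plus cos(pi * k * (t + 1/2) / N) for
    k = 1 .. floor(2 * N * TR / cutoff); component k has period 2*N*TR/k, so
    the basis spans exactly the sub-cutoff frequencies. Columns are
    orthonormal.
    """
    if n_scans < 2:
        raise ValueError("need >= 2 time points")
    if cutoff_s <= 2 * tr_s:
        raise ValueError(f"cutoff {cutoff_s} s must exceed 2 * TR = {2 * tr_s} s")
    order = int(np.floor(2.0 * n_scans * tr_s / cutoff_s))
    n = np.arange(n_scans)
    cols = [np.full(n_scans, 1.0 / np.sqrt(n_scans))]
    for k in range(1, order + 1):
        c = np.cos(np.pi * k * (n + 0.5) / n_scans)
        cols.append(c * np.sqrt(2.0 / n_scans))
    return np.column_stack(cols)


def dct_highpass_project(timeseries: np.ndarray, tr_s: float,
                         cutoff_s: float = 128.0) -> np.ndarray:
    """Remove slow drifts: project out the DCT basis with period > cutoff_s.

    ``timeseries`` is (n_scans,) or (n_scans, n_series). The projection is
    idempotent and removes the constant, so filtered series are mean-free.
    """
    x = np.asarray(timeseries, dtype=float)
    ts = x.reshape(x.shape[0], -1)
    basis = dct_highpass_basis(ts.shape[0], tr_s, cutoff_s)
    filtered = ts - basis @ (basis.T @ ts)
    return filtered.reshape(x.shape)
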