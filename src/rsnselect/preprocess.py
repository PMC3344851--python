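"""Temporal detrending / high-pass filtering and spatial Gaussian smoothing.

The high-pass step removes the voxelwise mean, the linear trend and all
fluctuations slower than the cutoff by projecting each in-mask time course
onto the orthogonal complement of a discrete-cosine basis (the common fMRI
practice; avoids the wraparound artifacts of Fourier masking).  Smoothing
convolves each volume with an isotropic-in-mm Gaussian kernel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BoldRun

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class PreprocParams:
    highpass_hz: float = 0.005
    fwhm_mm: float = 8.0
    detrend: bool = True

    def __post_init__(self):
        if self.highpass_hz < 0:
            raise ValueError("highpass_hz must be >= 0")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm_mm must be >= 0")


def _slow_basis(n, tr_seconds, highpass_hz, detrend):
    """Columns spanning the removed subspace: intercept, linear trend and
    DCT-II cosines with frequency <= highpass_hz."""
    cols = [np.ones(n)]
    if detrend:
        cols.append(np.linspace(-1.0, 1.0, n))
    # DCT-II frequency of basis function k is k / (2 N TR)
    k_max = int(np.floor(2.0 * n * tr_seconds * highpass_hz))
    t = (np.arange(n) + 0.5) / n
    for k in range(1, k_max + 1):
        cols.append(np.cos(np.pi * k * t))
    return np.column_stack(cols)


def detrend_highpass(run: BoldRun, params: PreprocParams = None) -> BoldRun:
    """Remove mean, linear trend and all frequency content below the cutoff
    from every in-mask voxel; out-of-mask voxels are untouched."""
    params = params or PreprocParams()
    nyquist = 0.5 / run.tr_seconds
    if params.highpass_hz >= nyquist:
        raise ValueError(
            f"highpass {params.highpass_hz} Hz >= Nyquist {nyquist} Hz")
    B = _slow_basis(run.n_volumes, run.tr_seconds, params.highpass_hz,
                    params.detrend)
    Q, _ = np.linalg.qr(B)
    X = run.in_mask()                       # (t, v)
    Xc = X - Q @ (Q.T @ X)
    data = run.data.copy()
    data[run.mask] = Xc.T
    return run.with_data(data)


def smooth_gaussian(run: BoldRun, params: PreprocParams = None) -> BoldRun:
    """Convolve each volume with an isotropic Gaussian of the given FWHM
    (in mm; converted per axis to voxels), nearest-edge replication at the
    grid boundary."""
    params = params or PreprocParams()
    if params.fwhm_mm == 0:
        return run.with_data(run.data.copy())
    sigmas = tuple(params.fwhm_mm * FWHM_TO_SIGMA / v for v in run.voxel_mm)
    data = ndimage.gaussian_filter(run.data, sigma=sigmas + (0.0,),
                                   mode="nearest")
    return run.with_data(data)


def preprocess(run: BoldRun, params: PreprocParams = None) -> BoldRun:
    """Standard order: filter first, then smooth."""
    params = params or PreprocParams()
    return smooth_gaussian(detrend_highpass(run, params), params)
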