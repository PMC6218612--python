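"""Spectral prewhitening of voxel/region time series.

Autocorrelated, non-stationary series inflate zero-lag cross-correlations.
Flattening the discrete Fourier magnitude spectrum — dividing each DFT bin
by its modulus — makes the power spectrum flat, so the circular
autocorrelation becomes an impulse, as for white noise. The transform is
a-causal and circular by construction; no tapering is applied, and the DFT
length equals the series length (no zero-padding).

The DC bin is always zeroed: band-passed resting-state data are mean-free,
and a zero-mean output makes downstream cosine similarity equal the
Pearson correlation. Bins whose magnitude is (numerically) zero carry no
energy at that frequency; they are mapped to zero rather than to unit
magnitude, so no energy is injected at frequencies absent from the data.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .synthetic import VoxelDataset

__all__ = ["prewhiten_series", "prewhiten_dataset"]

DEFAULT_ZERO_TOL = 1e-12


def prewhiten_series(x: np.ndarray, zero_tol: float = DEFAULT_ZERO_TOL) -> np.ndarray:
    """Flatten the magnitude spectrum of a real series.

    Parameters
    ----------
    x : real sequence, length T >= 2
    zero_tol : relative tolerance; DFT bins with modulus <= zero_tol times
        the maximum modulus are zeroed instead of normalized.

    Returns
    -------
    Real series of length T whose DFT has modulus exactly 1 on every
    retained bin and 0 on the DC bin and any zeroed bins.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("input must be a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("input series contains non-finite values")
    spec = np.fft.fft(x)
    mags = np.abs(spec)
    if not np.any(mags[1:] > 0):
        raise ValueError("all-zero input: no spectrum to flatten")
    keep = mags > zero_tol * mags.max()
    keep[0] = False  # DC always zeroed
    out = np.zeros_like(spec)
    out[keep] = spec[keep] / mags[keep]
    return np.fft.ifft(out).real


def prewhiten_dataset(dataset: VoxelDataset,
                      zero_tol: float = DEFAULT_ZERO_TOL) -> VoxelDataset:
    """Prewhiten every voxel column independently; shape and metadata are
    preserved. Per-series errors are re-raised with the voxel index."""
    cols = []
    for j in range(dataset.n_voxels):
        try:
            cols.append(prewhiten_series(dataset.series[:, j], zero_tol))
        except ValueError as exc:
            raise ValueError(f"voxel {j}: {exc}") from exc
    return replace(dataset, series=np.column_stack(cols))
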