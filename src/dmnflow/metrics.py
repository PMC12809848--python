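"""Network-level Shannon entropy and voxel-level homogeneity/entropy maps.

Shannon entropy here is the histogram (marginal-distribution) entropy of a
BOLD time series: amplitudes are binned into equal-width bins spanning
[min, max] and H = -sum p_i ln p_i over occupied bins, in nats. Because it
depends only on the amplitude distribution, the measure is invariant to
temporal reordering and to affine rescaling of the series.

Network homogeneity (NH) assigns each voxel of a network mask the mean
Pearson correlation of its time series with every other voxel in the mask.
NH maps are converted to z-maps by the Fisher r-to-z transform; entropy maps
by within-mask standardization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EntropyResult",
    "NHMap",
    "shannon_entropy",
    "network_homogeneity_map",
    "voxel_entropy_map",
    "fisher_z",
    "standardize_entropy_map",
]


@dataclass
class EntropyResult:
    entropy_nats: float
    n_bins: int
    n_samples: int


@dataclass
class NHMap:
    raw: np.ndarray  # 3D, mean correlation per mask voxel (0 outside)
    z: np.ndarray  # 3D, Fisher-z per mask voxel
    mask: np.ndarray  # 3D bool


def shannon_entropy(series: np.ndarray, n_bins: int = 32) -> EntropyResult:
    """Histogram Shannon entropy of a time series, in nats.

    Equal-width bins span [min, max]; H = -sum p_i ln p_i over nonempty bins,
    so 0 <= H <= ln(n_bins).
    """
    series = np.asarray(series, dtype=float).reshape(-1)
    if series.size < n_bins:
        raise ValueError("series shorter than the number of bins")
    if np.ptp(series) == 0:
        raise ValueError("constant series: histogram entropy undefined (zero range)")
    counts, _ = np.histogram(series, bins=n_bins)
    p = counts[counts > 0] / series.size
    h = float(-np.sum(p * np.log(p)))
    return EntropyResult(entropy_nats=h, n_bins=n_bins, n_samples=series.size)


def network_homogeneity_map(image: np.ndarray, mask: np.ndarray) -> NHMap:
    """Voxel-wise mean correlation with all other voxels in the network mask.

    Computed from row sums of the full correlation matrix:
    NH(v) = (sum_u C[v, u] - 1) / (m - 1). Constant voxels get all their
    correlations set to 0 (with a warning) rather than NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    m = int(mask.sum())
    if m < 2:
        raise ValueError("mask must contain at least 2 voxels")
    data = image.reshape(-1, image.shape[-1])[mask.reshape(-1)]  # (m, T)
    sds = data.std(axis=1)
    constant = sds == 0
    if constant.any():
        warnings.warn(
            f"{constant.sum()} constant voxel(s) in mask; correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    nh = (corr.sum(axis=1) - 1.0) / (m - 1)
    nh[constant] = 0.0

    raw = np.zeros(mask.shape)
    raw[mask] = nh
    z = np.zeros(mask.shape)
    z[mask] = fisher_z(nh)
    return NHMap(raw=raw, z=z, mask=mask)


def voxel_entropy_map(
    image: np.ndarray, mask: np.ndarray, n_bins: int = 32
) -> np.ndarray:
    """Per-voxel histogram entropy within the mask; constant voxels get NaN."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    data = image.reshape(-1, image.shape[-1])[mask.reshape(-1)]
    out_vals = np.full(data.shape[0], np.nan)
    for i, ts in enumerate(data):
        if np.ptp(ts) == 0:
            continue  # flagged missing
        out_vals[i] = shannon_entropy(ts, n_bins).entropy_nats
    out = np.full(mask.shape, np.nan)
    out[mask] = out_vals
    return out


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform with |r| clipped to 1 - 1e-7 for finiteness."""
    return np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))


def standardize_entropy_map(entropy_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Within-mask standardization of an entropy map (mean 0, SD 1 in mask).

    NaN voxels (constant time series) are ignored when computing the moments
    and remain NaN in the output.
    """
    mask = np.asarray(mask, dtype=bool)
    vals = entropy_map[mask]
    finite = np.isfinite(vals)
    if finite.sum() < 2 or np.nanstd(vals) == 0:
        raise ValueError("entropy map has zero variance within mask")
    mu, sd = np.nanmean(vals), np.nanstd(vals)
    out = np.full(entropy_map.shape, 0.0)
    out[mask] = (entropy_map[mask] - mu) / sd
    out[~mask] = 0.0
    return out
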