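"""Voxel-level regional homogeneity (ReHo) mapping.

ReHo quantifies local functional connectivity as Kendall's coefficient of
concordance (KCC, W) between a voxel's time series and those of its 26
face/edge/corner neighbours.  For K series of n time points with within-series
ranks summed across series at each time point (R_i, with mean Rbar =
(n+1)K/2):

    W = (sum_i R_i^2 - n * Rbar^2) / ((1/12) * K^2 * (n^3 - n))

W ranges from 0 (no concordance) to 1 (identical rank orderings).  Ties take
average ranks; no tie-correction term is applied in the denominator (BOLD
floats make exact ties measure-zero).

The map pipeline is: raw W map -> division by the within-mask global mean ->
Gaussian smoothing (4 mm FWHM default).  Smoothing deliberately comes after
the W computation so that it cannot inflate neighbourhood concordance.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
from scipy import ndimage, stats

from .types import BoldSeries, ReHoMap

logger = logging.getLogger(__name__)

__all__ = [
    "compute_kcc",
    "reho_map",
    "normalize_global_mean",
    "smooth_gaussian",
    "fwhm_to_sigma_voxels",
]

#: FWHM = sigma * sqrt(8 ln 2)
_FWHM_PER_SIGMA = float(np.sqrt(8.0 * np.log(2.0)))


def compute_kcc(time_series_set: np.ndarray) -> float:
    """Kendall's coefficient of concordance over a K x n series matrix.

    Rows are series, columns are time points.  Returns W in [0, 1]; an
    all-constant set (undefined rank agreement) returns 0 with a warning.
    """
    ts = np.asarray(time_series_set, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError(f"expected a K x n matrix, got shape {ts.shape}")
    k, n = ts.shape
    if k < 2 or n < 2:
        raise ValueError(f"need K >= 2 and n >= 2, got K={k}, n={n}")
    if np.all(ts == ts[:, :1]):
        logger.warning("all series constant: concordance undefined, returning 0")
        return 0.0
    ranks = stats.rankdata(ts, axis=1)  # average ranks on ties
    r_i = ranks.sum(axis=0)
    rbar = (n + 1) * k / 2.0
    numerator = float(np.sum(r_i**2)) - n * rbar**2
    denominator = (k * k * (n**3 - n)) / 12.0
    return float(numerator / denominator)


def _neighbor_sum(arr: np.ndarray) -> np.ndarray:
    """Sum over the 3x3x3 neighbourhood (incl. centre) of the leading 3 axes.

    Works for 3D arrays (mask counts) and 4D arrays (rank volumes); values
    outside the grid contribute 0.
    """
    spatial_pad = [(1, 1)] * 3 + [(0, 0)] * (arr.ndim - 3)
    padded = np.pad(arr, spatial_pad, mode="constant")
    out = np.zeros_like(arr, dtype=np.float64)
    nx, ny, nz = arr.shape[:3]
    for dx, dy, dz in itertools.product((0, 1, 2), repeat=3):
        out += padded[dx : dx + nx, dy : dy + ny, dz : dz + nz]
    return out


def reho_map(
    series: BoldSeries,
    mask: np.ndarray,
    edge_policy: str = "subset",
) -> ReHoMap:
    """Voxelwise Kendall's W over each voxel's 27-voxel neighbourhood.

    For each in-mask voxel, W is computed over the voxel plus the in-mask
    subset of its 26 nearest neighbours (K = 1 + in-mask neighbour count).

    Parameters
    ----------
    edge_policy : {"subset", "full"}
        "subset" keeps boundary voxels, using their actual in-mask K;
        "full" zeroes voxels lacking the complete 27-voxel neighbourhood.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ValueError(
            f"mask shape {mask.shape} != series grid {series.grid_shape}"
        )
    if not np.any(mask):
        raise ValueError("empty mask")
    if edge_policy not in ("subset", "full"):
        raise ValueError(f"unknown edge_policy {edge_policy!r}")

    n = series.n_timepoints
    # Within-series temporal ranks for in-mask voxels; zeros elsewhere so
    # out-of-mask voxels never contribute to a neighbourhood sum.
    ranks = np.zeros(series.data.shape, dtype=np.float64)
    ranks[mask] = stats.rankdata(series.data[mask], axis=-1)

    k_count = _neighbor_sum(mask.astype(np.float64))  # in-mask K per voxel
    r_sum = _neighbor_sum(ranks)  # R_i per voxel and time point

    rbar = (n + 1) * k_count / 2.0
    numerator = np.sum(r_sum**2, axis=-1) - n * rbar**2
    denominator = (k_count * k_count * (n**3 - n)) / 12.0

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(denominator > 0, numerator / denominator, 0.0)
    valid = mask & (k_count >= 2)
    if edge_policy == "full":
        valid &= k_count == 27
    w = np.where(valid, w, 0.0)
    # Constant in-mask series produce a 0/positive-denominator numerator of 0
    # already (all ranks tie at (n+1)/2), so no special-casing is needed.
    return ReHoMap(
        values=w,
        mask=mask,
        stage="raw",
        subject_id=series.subject_id,
        affine=series.affine,
    )


def normalize_global_mean(reho: ReHoMap) -> ReHoMap:
    """Divide by the within-mask global mean, making the in-mask mean 1."""
    mean = reho.in_mask_mean()
    if mean <= 0:
        raise ValueError(f"in-mask mean {mean} is not positive; cannot normalize")
    values = np.where(reho.mask, reho.values / mean, 0.0)
    return ReHoMap(
        values=values,
        mask=reho.mask,
        stage="normalized",
        subject_id=reho.subject_id,
        affine=reho.affine,
    )


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_sizes_mm: np.ndarray) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    return fwhm_mm / (_FWHM_PER_SIGMA * np.asarray(voxel_sizes_mm, dtype=float))


def smooth_gaussian(
    reho: ReHoMap, fwhm_mm: float = 4.0, remask: bool = True
) -> ReHoMap:
    """Gaussian smoothing of a normalized ReHo map.

    The kernel width is specified as full-width at half-maximum in mm and
    converted per axis through the map's voxel sizes (anisotropic voxels get
    per-axis sigmas).  Values outside the mask are not re-zeroed before
    convolution; by default the output is re-masked afterwards.
    """
    if reho.stage != "normalized":
        raise ValueError(
            f"smoothing expects a normalized map, got stage {reho.stage!r}"
        )
    if fwhm_mm <= 0:
        warnings.warn("fwhm_mm <= 0: smoothing is the identity", stacklevel=2)
        values = reho.values.copy()
    else:
        sigma = fwhm_to_sigma_voxels(fwhm_mm, reho.voxel_sizes_mm)
        values = ndimage.gaussian_filter(reho.values, sigma=sigma, mode="reflect")
    if remask:
        values = np.where(reho.mask, values, 0.0)
    return ReHoMap(
        values=values,
        mask=reho.mask,
        stage="smoothed",
        subject_id=reho.subject_id,
        affine=reho.affine,
    )
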