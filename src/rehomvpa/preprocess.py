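"""Temporal preprocessing of normalized BOLD series.

Covers the post-normalization stages only: nuisance regression (Friston-24
motion expansion, white-matter, CSF and global signals), first-order
detrending, 0.01-0.08 Hz band-pass filtering, and the framewise-displacement
head-motion gate.  Spatial steps (slice timing, realignment estimation,
normalization, segmentation) are assumed done upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import BoldSeries, SubjectRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ConfoundSet",
    "friston24",
    "fd_power",
    "exclude_by_motion",
    "regress_confounds",
    "detrend_linear",
    "bandpass",
    "preprocess_series",
]

#: Head radius (mm) used to convert rotations to arc length in the
#: framewise-displacement metric.
DEFAULT_ROTATION_RADIUS_MM = 50.0


def friston24(motion6: np.ndarray) -> np.ndarray:
    """Friston-24 expansion of 6 rigid-body motion parameters.

    Columns are [p, p^2, p(t-1), p(t-1)^2] blocks of 6; the lagged terms of
    the first row are set to 0.
    """
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"motion parameters must be T x 6; got shape {motion6.shape}")
    lagged = np.vstack([np.zeros((1, 6)), motion6[:-1]])
    return np.hstack([motion6, motion6**2, lagged, lagged**2])


@dataclass
class ConfoundSet:
    """Nuisance regressors for one subject, all of length T."""

    motion24: np.ndarray
    wm_signal: np.ndarray
    csf_signal: np.ndarray
    global_signal: np.ndarray

    def __post_init__(self) -> None:
        self.motion24 = np.asarray(self.motion24, dtype=np.float64)
        for name in ("wm_signal", "csf_signal", "global_signal"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64).ravel())
        t = self.motion24.shape[0]
        if self.motion24.ndim != 2 or self.motion24.shape[1] != 24:
            raise ValueError(f"motion24 must be T x 24; got {self.motion24.shape}")
        for name in ("wm_signal", "csf_signal", "global_signal"):
            if getattr(self, name).shape[0] != t:
                raise ValueError(f"{name} length != T ({t})")

    @property
    def n_timepoints(self) -> int:
        return self.motion24.shape[0]

    def design(self) -> np.ndarray:
        """T x 27 confound matrix (no intercept)."""
        return np.column_stack(
            [self.motion24, self.wm_signal, self.csf_signal, self.global_signal]
        )

    @classmethod
    def from_series(
        cls,
        series: BoldSeries,
        motion6: np.ndarray,
        brain_mask: np.ndarray,
        wm_mask: np.ndarray | None = None,
        csf_mask: np.ndarray | None = None,
    ) -> "ConfoundSet":
        """Build confounds from raw motion parameters and tissue masks.

        Absent WM/CSF masks yield zero columns, which the regression drops.
        """
        t = series.n_timepoints

        def mean_sig(mask: np.ndarray | None) -> np.ndarray:
            if mask is None or not np.any(mask):
                return np.zeros(t)
            return series.data[np.asarray(mask, bool)].mean(axis=0)

        return cls(
            motion24=friston24(motion6),
            wm_signal=mean_sig(wm_mask),
            csf_signal=mean_sig(csf_mask),
            global_signal=mean_sig(brain_mask),
        )


def fd_power(
    motion6: np.ndarray, rotation_radius_mm: float = DEFAULT_ROTATION_RADIUS_MM
) -> tuple[np.ndarray, float]:
    """Framewise displacement (Power): per-volume head motion in mm.

    FD(t) is the sum of absolute backward differences of the three
    translations (mm) and three rotations (radians, converted to arc length
    on a sphere of ``rotation_radius_mm``); FD(1) = 0.

    Returns
    -------
    (fd, mean_fd) : length-T array and its mean.
    """
    motion6 = np.asarray(motion6, dtype=np.float64)
    if motion6.ndim != 2 or motion6.shape[1] != 6:
        raise ValueError(f"motion parameters must be T x 6; got shape {motion6.shape}")
    if motion6.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute framewise displacement")
    diffs = np.abs(np.diff(motion6, axis=0))
    diffs[:, 3:] *= rotation_radius_mm
    fd = np.concatenate([[0.0], diffs.sum(axis=1)])
    return fd, float(fd.mean())


def exclude_by_motion(
    records: list[SubjectRecord], threshold_mm: float = 0.2
) -> tuple[list[SubjectRecord], dict]:
    """Drop subjects whose mean FD strictly exceeds the threshold.

    Returns the retained records and a report dict with the excluded ids and
    the threshold applied.
    """
    retained = [r for r in records if r.fd_power <= threshold_mm]
    excluded = [r for r in records if r.fd_power > threshold_mm]
    report = {
        "threshold_mm": threshold_mm,
        "n_input": len(records),
        "n_retained": len(retained),
        "excluded_ids": [r.subject_id for r in excluded],
        "excluded_fd": [r.fd_power for r in excluded],
    }
    return retained, report


def _drop_collinear(design: np.ndarray) -> np.ndarray:
    """Remove columns that add no rank (zero or linearly dependent)."""
    keep: list[int] = []
    rank = 0
    for j in range(design.shape[1]):
        cand = design[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            logger.warning("dropping collinear/zero confound column %d", j)
    return design[:, keep]


def _residualize(stack: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of each row of ``stack`` (V x T) on ``design`` (T x k)."""
    beta, *_ = np.linalg.lstsq(design, stack.T, rcond=None)
    return stack - (design @ beta).T


def regress_confounds(series: BoldSeries, confounds: ConfoundSet) -> BoldSeries:
    """Voxelwise OLS removal of [intercept | confounds].

    Residuals are orthogonal to every retained regressor; rank-deficient
    designs lose their collinear columns with a logged warning.
    """
    if confounds.n_timepoints != series.n_timepoints:
        raise ValueError(
            f"confound length {confounds.n_timepoints} != series length "
            f"{series.n_timepoints}"
        )
    t = series.n_timepoints
    design = np.column_stack([np.ones(t), confounds.design()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        design = _drop_collinear(design)
    flat = series.data.reshape(-1, t)
    resid = _residualize(flat, design)
    return series.with_data(resid.reshape(series.data.shape))


def detrend_linear(series: BoldSeries) -> BoldSeries:
    """Remove the per-voxel best-fit line (intercept + slope) in time."""
    if series.n_timepoints < 3:
        raise ValueError("need at least 3 time points to detrend")
    data = signal.detrend(series.data, axis=-1, type="linear")
    return series.with_data(data)


def bandpass(
    series: BoldSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> BoldSeries:
    """Ideal (frequency-domain) zero-phase band-pass filter.

    Fourier components outside [low_hz, high_hz] are zeroed and the series
    inverse-transformed — the filter style of the classic resting-state
    toolboxes.  It is exactly zero-phase (no temporal shift that would
    distort rank order and bias Kendall's W downstream) and exactly
    idempotent: reapplying it changes nothing.
    """
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0.0 < low_hz < high_hz < nyquist):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for TR {series.tr_seconds}s "
            f"(Nyquist = {nyquist:g} Hz)"
        )
    n = series.n_timepoints
    freqs = np.fft.rfftfreq(n, d=series.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(series.data, axis=-1)
    spec[..., ~keep] = 0.0
    data = np.fft.irfft(spec, n=n, axis=-1)
    return series.with_data(data)


def preprocess_series(
    series: BoldSeries,
    confounds: ConfoundSet | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> BoldSeries:
    """Nuisance regression -> linear detrend -> band-pass, in that order."""
    if confounds is not None:
        series = regress_confounds(series, confounds)
    series = detrend_linear(series)
    return bandpass(series, low_hz=low_hz, high_hz=high_hz)
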