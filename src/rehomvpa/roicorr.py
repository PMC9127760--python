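"""Covariate-adjusted ROI-symptom correlation.

The discriminative clusters become regions of interest; each subject's mean
smoothed-ReHo value per ROI is correlated with depression severity (HDRS-17)
by partial Pearson correlation, controlling for the clinical covariates
(age, sex, education, tremor scores, MMSE, anxiety, head motion), with
Bonferroni control across ROIs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .permutation import ClusterROI
from .types import ReHoMap, SubjectRecord

__all__ = [
    "extract_roi_means",
    "partial_pearson",
    "bonferroni_threshold",
    "z_transform",
    "roi_symptom_correlation",
    "DEFAULT_COVARIATES",
]

#: Covariates controlled in the ROI-symptom analysis.
DEFAULT_COVARIATES = (
    "age",
    "sex",
    "education",
    "trs_ab",
    "trs_c",
    "mmse",
    "hars14",
    "fd_power",
)


def extract_roi_means(
    maps: list[ReHoMap], clusters: list[ClusterROI]
) -> pd.DataFrame:
    """Per-subject arithmetic mean map value over each cluster's voxels.

    Returns a subjects x ROIs DataFrame indexed by subject id.
    """
    if not clusters:
        raise ValueError("no clusters given")
    for c in clusters:
        if c.size == 0:
            raise ValueError(f"cluster {c.label!r} is empty")
    rows = {}
    for m in maps:
        vals = [float(m.values[tuple(c.voxels.T)].mean()) for c in clusters]
        rows[m.subject_id] = vals
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[c.label for c in clusters]
    )


def partial_pearson(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y controlling for covariates.

    Both variables are residualized by OLS on [intercept | covariates]; r is
    the plain Pearson correlation of the residuals and the two-tailed p comes
    from t = r * sqrt(df / (1 - r^2)) with df = n - k - 2 for k covariates.
    With no covariates this reduces exactly to the ordinary Pearson r.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y lengths differ")
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        z = np.ones((n, 1))
        k = 0
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if covariates.shape[0] != n:
            covariates = covariates.T
        if covariates.shape[0] != n:
            raise ValueError("covariate rows do not match n")
        z = np.column_stack([np.ones(n), covariates])
        k = covariates.shape[1]
    df = n - k - 2
    if df <= 0:
        raise ValueError(f"not enough observations: n={n}, covariates={k}")
    beta_x, *_ = np.linalg.lstsq(z, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(z, y, rcond=None)
    rx = x - z @ beta_x
    ry = y - z @ beta_y
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx < 1e-12 * max(1.0, np.linalg.norm(x)) or sy < 1e-12 * max(1.0, np.linalg.norm(y)):
        warnings.warn(
            "constant residuals: partial correlation undefined", stacklevel=2
        )
        return float("nan"), float("nan")
    r = float(rx @ ry / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bonferroni_threshold(alpha: float, m: int, mode: str = "tests") -> float:
    """Bonferroni-corrected per-test significance threshold.

    ``mode="tests"`` divides by the number of tests m; ``mode="pairwise"``
    divides by m*(m-1)/2 (the all-pairs comparison count for m items).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if mode == "tests":
        return alpha / m
    if mode == "pairwise":
        return alpha / (m * (m - 1) / 2) if m > 1 else alpha
    raise ValueError(f"unknown mode {mode!r}")


def z_transform(scores: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample SD 1 (ddof=1)."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if len(scores) < 2:
        raise ValueError("need at least 2 values")
    sd = scores.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-transform undefined")
    return (scores - scores.mean()) / sd


def roi_symptom_correlation(
    roi_table: pd.DataFrame,
    records: list[SubjectRecord],
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    alpha: float = 0.05,
    bonferroni_mode: str = "tests",
) -> pd.DataFrame:
    """Partial correlation of each ROI's mean smReHo with HDRS-17.

    ``records`` supplies the symptom scores and covariates; only subjects
    present in both the ROI table and the records enter (order follows the
    ROI table).  Returns one row per ROI with r, uncorrected p, the
    corrected threshold and a pass flag.
    """
    by_id = {r.subject_id: r for r in records}
    ids = [s for s in roi_table.index if s in by_id]
    if len(ids) < len(covariates) + 3:
        raise ValueError(
            f"only {len(ids)} subjects for {len(covariates)} covariates"
        )
    y = np.array([by_id[s].hdrs17 for s in ids], dtype=float)
    cov = np.column_stack(
        [[getattr(by_id[s], c) for s in ids] for c in covariates]
    ) if covariates else None
    m = roi_table.shape[1]
    threshold = bonferroni_threshold(alpha, m, mode=bonferroni_mode)
    out = []
    for roi in roi_table.columns:
        x = roi_table.loc[ids, roi].to_numpy(dtype=float)
        r, p = partial_pearson(x, y, cov)
        out.append(
            {
                "roi": roi,
                "r": r,
                "p_uncorrected": p,
                "p_threshold_corrected": threshold,
                "significant": bool(p < threshold) if np.isfinite(p) else False,
                "n_effective": len(ids),
            }
        )
    return pd.DataFrame(out).set_index("roi")
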