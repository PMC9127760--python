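"""Core in-memory containers shared by all pipeline stages.

The pipeline passes three kinds of objects between stages: a subject's 4D
BOLD series, a subject's 3D regional-homogeneity map, and a subject's
clinical/demographic record.  All three are light dataclasses around numpy
arrays / plain scalars; file I/O lives in :mod:`rehomvpa.io`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: The three cohort groups: depressed essential tremor, non-depressed
#: essential tremor, healthy controls.
GROUPS = ("DET", "ET", "HC")

#: ReHo map processing stages, in pipeline order.
REHO_STAGES = ("raw", "normalized", "smoothed")


def _default_affine() -> np.ndarray:
    """3 mm isotropic grid centered at the origin-corner voxel."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = 3.0
    return aff


@dataclass
class BoldSeries:
    """One subject's spatially normalized 4D BOLD volume.

    Parameters
    ----------
    data : ndarray, shape (X, Y, Z, T)
        Voxel time series in arbitrary signal units.
    tr_seconds : float
        Repetition time in seconds.
    affine : ndarray, shape (4, 4)
        Voxel-grid-to-millimetre transform.
    subject_id : str
    """

    data: np.ndarray
    tr_seconds: float
    affine: np.ndarray = field(default_factory=_default_affine)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"BoldSeries.data must be 4D (X,Y,Z,T); got shape {self.data.shape}"
            )
        if self.data.shape[3] < 20:
            raise ValueError(
                f"BoldSeries needs at least 20 time points; got {self.data.shape[3]}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"non-finite values in BOLD data for subject {self.subject_id!r}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (norm of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Copy of this series with ``data`` replaced (metadata kept)."""
        return dataclasses.replace(self, data=data)


@dataclass
class ReHoMap:
    """A voxelwise Kendall's-W (regional homogeneity) map.

    ``stage`` records where the map sits in the raw -> global-mean
    normalized -> Gaussian-smoothed chain; downstream stages check it.
    """

    values: np.ndarray
    mask: np.ndarray
    stage: str = "raw"
    subject_id: str = ""
    affine: np.ndarray = field(default_factory=_default_affine)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("ReHoMap.values must be 3D")
        if self.values.shape != self.mask.shape:
            raise ValueError(
                f"values shape {self.values.shape} != mask shape {self.mask.shape}"
            )
        if self.stage not in REHO_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {REHO_STAGES}")

    @property
    def voxel_sizes_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def in_mask_mean(self) -> float:
        return float(self.values[self.mask].mean())


@dataclass
class SubjectRecord:
    """Clinical/demographic record for one subject.

    HDRS-17 is the 17-item Hamilton depression scale (>= 7 defines the
    depressed group); HARS-14 the Hamilton anxiety scale; TRS the
    Fahn-Tolosa-Marin tremor rating scale (parts A&B and C); TETRAS an
    alternative tremor scale; fd_power the mean framewise displacement in mm.
    Sex is coded 0 = female, 1 = male.
    """

    subject_id: str
    group: str
    hdrs17: float
    hars14: float = 0.0
    mmse: float = 0.0
    trs_ab: float = 0.0
    trs_c: float = 0.0
    tetras: float = 0.0
    age: float = 0.0
    education: float = 0.0
    sex: int = 0
    fd_power: float = 0.0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.hdrs17 < 0:
            raise ValueError("hdrs17 must be non-negative")
        if self.group == "DET" and self.hdrs17 < 7:
            raise ValueError(
                f"DET subject {self.subject_id!r} has HDRS-17 {self.hdrs17} < 7"
            )
        if self.fd_power < 0:
            raise ValueError("fd_power must be non-negative")
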