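"""Synthetic three-group resting-state cohort generator.

Emulates a cohort of depressed essential-tremor patients (DET), non-depressed
essential-tremor patients (ET) and healthy controls (HC): per-subject 4D
BOLD-like volumes with temporally autocorrelated noise, regionally implanted
local temporal coherence that differs by group, and clinical covariates drawn
to match the published group means and standard deviations.

The coherence mechanism targets exactly the property that regional
homogeneity measures.  Inside each effect region, every voxel's series is

    sqrt(c) * shared_regional_series + sqrt(1 - c) * private_noise

with both components stationary AR(1) processes of unit variance, so ``c``
is the fraction of voxel variance carried by the shared regional signal and
Kendall's W inside the box increases monotonically with ``c``.

A subject's realized coherence deviates from the group value by a random
perturbation; depression severity (HDRS-17) is generated as the group base
score plus ``hdrs_coupling`` times that realized deviation plus noise, which
lets the ROI-symptom partial-correlation stage be tested as a
parameter-recovery problem.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal, stats

from .types import GROUPS, BoldSeries, SubjectRecord

__all__ = [
    "EffectRegion",
    "SyntheticConfig",
    "generate_clinical",
    "generate_cohort",
    "iter_cohort",
    "make_mask",
    "TABLE_MOMENTS",
]

# Published group means and standard deviations (DET, ET, HC) used to
# calibrate the clinical covariate generator.  ``lower`` is the truncation
# bound (scales cannot go negative; DET requires HDRS-17 >= 7).
TABLE_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "age": {"DET": (47.85, 15.66), "ET": (44.49, 13.73), "HC": (46.67, 13.16)},
    "education": {"DET": (14.73, 4.17), "ET": (12.40, 3.77), "HC": (12.22, 3.42)},
    "hdrs17": {"DET": (18.98, 6.35), "ET": (3.49, 1.56), "HC": (2.11, 1.17)},
    "mmse": {"DET": (26.00, 1.40), "ET": (26.33, 1.51), "HC": (28.67, 1.35)},
    "hars14": {"DET": (7.56, 3.47), "ET": (4.09, 1.66), "HC": (2.04, 1.17)},
    "trs_ab": {"DET": (22.66, 7.28), "ET": (20.93, 7.77), "HC": (0.0, 0.0)},
    "trs_c": {"DET": (14.05, 4.74), "ET": (10.70, 5.22), "HC": (0.0, 0.0)},
    "tetras": {"DET": (18.32, 8.27), "ET": (17.41, 6.79), "HC": (0.0, 0.0)},
}

#: Male fraction per group (males : females 26:15, 28:15, 28:17).
_MALE_FRACTION = {"DET": 26 / 41, "ET": 28 / 43, "HC": 28 / 45}

#: HDRS-17 truncation floor: >= 7 defines depression; other scores >= 0.
_HDRS_FLOOR = {"DET": 7.0, "ET": 0.0, "HC": 0.0}

#: Mean framewise displacement (mm): compliant subjects sample uniformly
#: below the 0.2 mm exclusion gate; injected high-motion subjects above it.
_FD_LOW = (0.05, 0.18)
_FD_HIGH = (0.21, 0.45)


@dataclass(frozen=True)
class EffectRegion:
    """An axis-aligned box with group-specific implanted temporal coherence.

    Parameters
    ----------
    voxel_box : three (lo, hi) pairs
        Half-open index ranges ``lo <= i < hi`` per axis.
    coherence_by_group : three floats in [0, 1]
        Shared-signal variance fraction for (DET, ET, HC); 0 means pure
        independent noise.
    hdrs_coupling : float
        HDRS-17 points added per unit of a subject's realized coherence
        deviation from the group value.
    """

    voxel_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    coherence_by_group: tuple[float, float, float]
    hdrs_coupling: float = 0.0

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.voxel_box)

    def coherence(self, group: str) -> float:
        return float(self.coherence_by_group[GROUPS.index(group)])

    def n_voxels(self) -> int:
        return int(np.prod([hi - lo for lo, hi in self.voxel_box]))

    def validate(self, grid_shape: tuple[int, int, int]) -> None:
        for axis, ((lo, hi), dim) in enumerate(zip(self.voxel_box, grid_shape)):
            if not (0 <= lo < hi <= dim):
                raise ValueError(
                    f"effect_regions: voxel_box axis {axis} range ({lo}, {hi}) "
                    f"does not fit inside grid dimension {dim}"
                )
        for c in self.coherence_by_group:
            if not (0.0 <= c <= 1.0):
                raise ValueError(
                    f"effect_regions: coherence_by_group value {c} outside [0, 1]"
                )


def _default_regions() -> list[EffectRegion]:
    # Anterior-superior box with DET-elevated coherence and positive symptom
    # coupling (prefrontal-like positive discriminative pattern), and a
    # posterior-inferior box with DET-reduced coherence and negative coupling
    # (cerebellar-like negative pattern).
    return [
        EffectRegion(((4, 10), (14, 20), (14, 20)), (0.60, 0.45, 0.30), 25.0),
        EffectRegion(((14, 20), (4, 10), (4, 10)), (0.20, 0.30, 0.45), -25.0),
    ]


@dataclass
class SyntheticConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions: group sizes 41/43/45, 230 retained
    volumes at TR = 2 s, and a 24x24x24 grid of 3 mm voxels.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_timepoints: int = 230
    tr_seconds: float = 2.0
    group_sizes: tuple[int, int, int] = (41, 43, 45)
    effect_regions: list[EffectRegion] = field(default_factory=_default_regions)
    noise_ar1: float = 0.3
    seed: int = 0
    #: SD of the per-subject, per-region coherence perturbation.
    coherence_jitter_sd: float = 0.1
    #: Subjects per group given above-threshold head motion (to exercise the
    #: exclusion gate); all others fall below 0.2 mm.
    n_high_motion: tuple[int, int, int] = (0, 0, 0)

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(d < 3 for d in self.grid_shape):
            raise ValueError(
                f"grid_shape: each dimension must be >= 3, got {self.grid_shape}"
            )
        if self.n_timepoints < 20:
            raise ValueError(f"n_timepoints: must be >= 20, got {self.n_timepoints}")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds: must be positive, got {self.tr_seconds}")
        if len(self.group_sizes) != 3 or any(n < 0 for n in self.group_sizes):
            raise ValueError(
                f"group_sizes: need 3 non-negative integers, got {self.group_sizes}"
            )
        if not (0.0 <= self.noise_ar1 < 1.0):
            raise ValueError(f"noise_ar1: must lie in [0, 1), got {self.noise_ar1}")
        for region in self.effect_regions:
            region.validate(tuple(self.grid_shape))
        for n_hm, n_grp in zip(self.n_high_motion, self.group_sizes):
            if n_hm < 0 or n_hm > n_grp:
                raise ValueError(
                    f"n_high_motion: {self.n_high_motion} exceeds group_sizes "
                    f"{self.group_sizes}"
                )

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = 3.0
        return aff

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        """Build a config from a plain mapping (e.g. a parsed YAML file)."""
        d = dict(d)
        for key in ("grid_shape", "group_sizes", "n_high_motion"):
            if key in d:
                d[key] = tuple(d[key])
        if "effect_regions" in d:
            regions = []
            for r in d["effect_regions"]:
                if isinstance(r, EffectRegion):
                    regions.append(r)
                else:
                    regions.append(
                        EffectRegion(
                            voxel_box=tuple(tuple(b) for b in r["voxel_box"]),
                            coherence_by_group=tuple(r["coherence_by_group"]),
                            hdrs_coupling=float(r.get("hdrs_coupling", 0.0)),
                        )
                    )
            d["effect_regions"] = regions
        return cls(**d)


def make_mask(config: SyntheticConfig) -> np.ndarray:
    """Analysis mask for a synthetic cohort: the full grid.

    Synthetic volumes carry signal everywhere (no simulated anatomy), so the
    mask keeps every voxel; edge-of-mask behaviour is exercised by passing
    restricted masks explicitly.
    """
    return np.ones(config.grid_shape, dtype=bool)


@functools.lru_cache(maxsize=None)
def _matched_mu(target_mean: float, sd: float, lower: float) -> float:
    """Location of a lower-truncated normal whose *truncated* mean hits target.

    Truncation pushes the observed mean above the location parameter, so
    sampling ``truncnorm(loc=target)`` would overshoot the published mean;
    we solve for the location that compensates.
    """
    if sd == 0:
        return target_mean

    def gap(mu: float) -> float:
        a = (lower - mu) / sd
        return stats.truncnorm.mean(a, np.inf, loc=mu, scale=sd) - target_mean

    lo, hi = target_mean - 8 * sd, target_mean + sd
    return float(optimize.brentq(gap, lo, hi, xtol=1e-10))


def _sample_truncated(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    mu = _matched_mu(mean, sd, lower)
    a = (lower - mu) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)


def _draw_record(
    rng: np.random.Generator, subject_id: str, group: str, high_motion: bool = False
) -> SubjectRecord:
    vals = {
        name: float(_sample_truncated(rng, 1, m, s, _HDRS_FLOOR[group] if name == "hdrs17" else 0.0)[0])
        for name, per_group in TABLE_MOMENTS.items()
        for m, s in [per_group[group]]
    }
    sex = int(rng.random() < _MALE_FRACTION[group])
    lo, hi = _FD_HIGH if high_motion else _FD_LOW
    fd = float(rng.uniform(lo, hi))
    return SubjectRecord(
        subject_id=subject_id, group=group, sex=sex, fd_power=fd, **vals
    )


def generate_clinical(group: str, n: int, seed: int) -> list[SubjectRecord]:
    """Draw ``n`` clinical records for one group from the calibrated model.

    Covariates are independent lower-truncated normals whose truncated means
    match the published group means (HDRS-17 floored at 7 for DET, 0
    otherwise; rating scales floored at 0); sex is Bernoulli at the published
    male fraction.  Sample moments converge to the published values as ``n``
    grows.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    return [_draw_record(rng, f"{group}{i + 1:03d}", group) for i in range(n)]


def _ar1(rng: np.random.Generator, shape: tuple[int, ...], phi: float, n_t: int) -> np.ndarray:
    """Stationary unit-variance AR(1) series along the last axis.

    Innovations are scaled so the stationary variance is 1; a 100-sample
    burn-in removes the transient from the zero initial state.
    """
    burn = 100
    innov = rng.standard_normal(shape + (n_t + burn,))
    if phi == 0.0:
        return innov[..., burn:]
    out = signal.lfilter([np.sqrt(1.0 - phi * phi)], [1.0, -phi], innov, axis=-1)
    return out[..., burn:]


def _simulate_subject(
    rng: np.random.Generator, config: SyntheticConfig, record: SubjectRecord
) -> tuple[BoldSeries, SubjectRecord]:
    """One subject's volume plus the symptom-coupled HDRS adjustment."""
    nx, ny, nz = config.grid_shape
    n_t = config.n_timepoints
    data = _ar1(rng, (nx, ny, nz), config.noise_ar1, n_t)

    hdrs_shift = 0.0
    for region in config.effect_regions:
        c_group = region.coherence(record.group)
        delta = float(rng.normal(0.0, config.coherence_jitter_sd))
        shared = _ar1(rng, (), config.noise_ar1, n_t)
        if c_group > 0.0:
            c_subj = float(np.clip(c_group + delta, 0.0, 0.999))
            sl = region.slices()
            data[sl] = np.sqrt(c_subj) * shared + np.sqrt(1.0 - c_subj) * data[sl]
            hdrs_shift += region.hdrs_coupling * (c_subj - c_group)
        # c_group == 0: pure independent noise, no symptom coupling

    if hdrs_shift != 0.0:
        floor = _HDRS_FLOOR[record.group]
        record.hdrs17 = float(max(floor, record.hdrs17 + hdrs_shift))

    series = BoldSeries(
        data=data,
        tr_seconds=config.tr_seconds,
        affine=config.affine(),
        subject_id=record.subject_id,
    )
    return series, record


def iter_cohort(config: SyntheticConfig):
    """Yield ``(BoldSeries, SubjectRecord)`` per subject, lazily.

    Identical output to :func:`generate_cohort` (per-subject RNG streams are
    spawned from the config seed, so draw order cannot leak between
    subjects) but holds only one volume in memory at a time.
    """
    config.validate()
    seed_seq = np.random.SeedSequence(config.seed)
    n_total = int(sum(config.group_sizes))
    children = seed_seq.spawn(n_total)
    idx = 0
    for group, n_group, n_hm in zip(GROUPS, config.group_sizes, config.n_high_motion):
        for i in range(n_group):
            rng = np.random.default_rng(children[idx])
            idx += 1
            record = _draw_record(
                rng, f"{group}{i + 1:03d}", group, high_motion=(i < n_hm)
            )
            yield _simulate_subject(rng, config, record)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[BoldSeries], list[SubjectRecord]]:
    """Materialize the full cohort (see :func:`iter_cohort` for streaming)."""
    series_list: list[BoldSeries] = []
    records: list[SubjectRecord] = []
    for series, record in iter_cohort(config):
        series_list.append(series)
        records.append(record)
    return series_list, records
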