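"""Temporal preprocessing: FD, motion gate, regression, detrend, band-pass."""

import numpy as np
import pytest
from scipy.signal import periodogram

import rehomvpa as rm
from rehomvpa.preprocess import friston24
from rehomvpa.types import SubjectRecord


def _series(data, tr=2.0):
    return rm.BoldSeries(data=data, tr_seconds=tr, subject_id="s1")


# ---------------------------------------------------------------- fd_power

def test_fd_zero_for_constant_motion():
    fd, mean = rm.fd_power(np.ones((30, 6)))
    assert np.all(fd == 0) and mean == 0


def test_fd_single_translation_step():
    t = 25
    motion = np.zeros((t, 6))
    motion[1:, 0] = 0.1  # one 0.1 mm step at volume 2
    fd, mean = rm.fd_power(motion)
    assert fd[1] == pytest.approx(0.1)
    assert mean == pytest.approx(0.1 / t)


def test_fd_matches_straight_line_recomputation(rng):
    motion = rng.normal(0, 0.05, (40, 6))
    fd, mean = rm.fd_power(motion, rotation_radius_mm=50.0)
    # independent element-by-element recomputation of the Power formula
    expect = [0.0]
    for t in range(1, 40):
        s = 0.0
        for j in range(6):
            d = abs(motion[t, j] - motion[t - 1, j])
            if j >= 3:
                d *= 50.0
            s += d
        expect.append(s)
    assert np.allclose(fd, expect, atol=1e-12)
    assert mean == pytest.approx(np.mean(expect), abs=1e-12)
    with pytest.raises(ValueError):
        rm.fd_power(motion[:, :5])


def test_friston24_layout():
    motion = np.arange(18, dtype=float).reshape(3, 6)
    f24 = friston24(motion)
    assert f24.shape == (3, 24)
    assert np.array_equal(f24[:, :6], motion)
    assert np.array_equal(f24[:, 6:12], motion**2)
    assert np.all(f24[0, 12:] == 0)  # first-row lagged terms zeroed
    assert np.array_equal(f24[1:, 12:18], motion[:-1])


# ------------------------------------------------------------ motion gate

def _rec(sid, fd):
    return SubjectRecord(subject_id=sid, group="HC", hdrs17=2.0, fd_power=fd)


def test_motion_gate_is_strictly_greater_than():
    records = [_rec("a", 0.19), _rec("b", 0.20), _rec("c", 0.21)]
    retained, report = rm.exclude_by_motion(records, 0.2)
    assert [r.subject_id for r in retained] == ["a", "b"]
    assert report["excluded_ids"] == ["c"]
    assert rm.exclude_by_motion([], 0.2)[0] == []


def test_motion_gate_on_injected_cohort():
    cfg = rm.SyntheticConfig(
        grid_shape=(4, 4, 4),
        n_timepoints=20,
        group_sizes=(8, 45, 48),
        effect_regions=[],
        n_high_motion=(3, 2, 3),
        seed=6,
    )
    records = [r for _, r in rm.iter_cohort(cfg)]
    retained, _ = rm.exclude_by_motion(records)
    counts = {g: sum(r.group == g for r in retained) for g in rm.GROUPS}
    assert counts == {"DET": 5, "ET": 43, "HC": 45}


# ------------------------------------------------------- confound regression

def _confounds(t, rng=None, zero=False):
    if zero:
        return rm.ConfoundSet(np.zeros((t, 24)), np.zeros(t), np.zeros(t), np.zeros(t))
    rng = rng or np.random.default_rng(0)
    return rm.ConfoundSet(
        rng.normal(size=(t, 24)), rng.normal(size=t), rng.normal(size=t), rng.normal(size=t)
    )


def test_regression_removes_perfectly_explained_voxel(rng):
    t = 40
    conf = _confounds(t, rng)
    data = np.tile(conf.global_signal, (2, 2, 2, 1))
    out = rm.regress_confounds(_series(data), conf)
    assert np.allclose(out.data, 0, atol=1e-10)


def test_regression_with_zero_confounds_demeans():
    t = 30
    data = np.random.default_rng(1).normal(size=(3, 3, 3, t))
    out = rm.regress_confounds(_series(data), _confounds(t, zero=True))
    assert np.allclose(out.data, data - data.mean(-1, keepdims=True), atol=1e-10)


def test_regression_matches_normal_equations_and_is_orthogonal(rng):
    t = 50
    conf = _confounds(t, rng)
    data = rng.normal(size=(2, 3, 2, t))
    out = rm.regress_confounds(_series(data), conf)
    design = np.column_stack([np.ones(t), conf.design()])
    # normal-equation oracle per voxel
    for idx in np.ndindex(2, 3, 2):
        y = data[idx]
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(out.data[idx], y - design @ beta, atol=1e-8)
    dots = np.abs(out.data.reshape(-1, t) @ design) / t
    assert dots.max() < 1e-8


# ---------------------------------------------------------------- detrend

def test_detrend_removes_lines_and_constants(rng):
    t = 40
    tt = np.arange(t, dtype=float)
    data = np.empty((2, 1, 1, t))
    data[0, 0, 0] = 2 * tt + 5
    data[1, 0, 0] = 3.3
    out = rm.detrend_linear(_series(data))
    assert np.allclose(out.data, 0, atol=1e-10)

    noisy = rng.normal(size=(2, 2, 2, t))
    out = rm.detrend_linear(_series(noisy))
    design = np.column_stack([np.ones(t), tt])
    for idx in np.ndindex(2, 2, 2):
        beta, *_ = np.linalg.lstsq(design, noisy[idx], rcond=None)
        assert np.allclose(out.data[idx], noisy[idx] - design @ beta, atol=1e-10)


# --------------------------------------------------------------- band-pass

def _sinusoid(freq, t=240, tr=2.0):
    time = np.arange(t) * tr
    return np.sin(2 * np.pi * freq * time)


def test_bandpass_preserves_in_band_sinusoid():
    sig = _sinusoid(0.04)
    data = np.tile(sig, (1, 1, 1, 1))
    out = rm.bandpass(_series(data)).data[0, 0, 0]
    core = slice(40, 200)  # avoid filter edge effects
    ratio = np.abs(out[core]).max() / np.abs(sig[core]).max()
    assert 0.95 < ratio < 1.05
    # zero phase: output stays in phase with the input sinusoid
    assert np.corrcoef(out[core], sig[core])[0, 1] > 0.99


def test_bandpass_suppresses_out_of_band_sinusoid():
    sig = _sinusoid(0.2)
    out = rm.bandpass(_series(sig[None, None, None, :])).data[0, 0, 0]
    core = slice(40, 200)
    assert np.abs(out[core]).max() < 0.1 * np.abs(sig[core]).max()


def test_bandpass_white_noise_spectral_mass(rng):
    data = rng.normal(size=(1, 1, 1, 512))
    out = rm.bandpass(_series(data)).data[0, 0, 0]
    f, pxx = periodogram(out, fs=0.5)
    in_band = (f >= 0.01) & (f <= 0.08)
    assert pxx[in_band].sum() / pxx.sum() >= 0.80


def test_bandpass_rejects_band_above_nyquist():
    with pytest.raises(ValueError, match="Nyquist"):
        rm.bandpass(_series(np.zeros((1, 1, 1, 30)), tr=10.0), 0.01, 0.08)


# ---------------------------------------------------- composed properties

def test_pipeline_nearly_idempotent(rng):
    """Re-running detrend+band-pass changes little.

    The band-pass is an exact projection (idempotent); the small residual
    comes from the detrend step, whose line subspace is not orthogonal to
    the pass band on a finite window (~1-2% RMS at these lengths).
    """
    data = rng.normal(size=(2, 2, 2, 230))
    once = rm.preprocess_series(_series(data))
    twice = rm.preprocess_series(once)
    rms = np.sqrt(np.mean(once.data**2))
    assert np.sqrt(np.mean((twice.data - once.data) ** 2)) < 0.03 * rms
    # the band-pass alone is exactly idempotent
    assert np.allclose(rm.bandpass(once).data, once.data, atol=1e-12)


def test_operations_commute_with_voxel_permutation(rng):
    data = rng.normal(size=(2, 2, 1, 64))
    perm = [(1, 0, 0), (0, 1, 0), (1, 1, 0), (0, 0, 0)]
    permuted = np.stack([data[i, j, k] for i, j, k in perm]).reshape(2, 2, 1, 64)
    out_orig = rm.preprocess_series(_series(data)).data
    out_perm = rm.preprocess_series(_series(permuted)).data
    back = np.stack([out_perm.reshape(4, 64)[i] for i in range(4)])
    expect = np.stack([out_orig[i, j, k] for i, j, k in perm])
    assert np.allclose(back, expect, atol=1e-12)
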