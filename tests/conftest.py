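import numpy as np
import pytest

import rehomvpa as rm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """8+8 subject two-group cohort with one strongly discriminable box."""
    cfg = rm.SyntheticConfig(
        grid_shape=(10, 10, 10),
        n_timepoints=60,
        group_sizes=(8, 0, 8),
        effect_regions=[rm.EffectRegion(((3, 9), (3, 9), (3, 9)), (0.8, 0.0, 0.1))],
        seed=7,
    )
    series, records = rm.generate_cohort(cfg)
    mask = rm.make_mask(cfg)
    return cfg, series, records, mask


@pytest.fixture(scope="session")
def small_cohort_features(small_cohort):
    """Smoothed ReHo feature matrix + labels for the small cohort."""
    _, series, records, mask = small_cohort
    maps = [
        rm.smooth_gaussian(rm.normalize_global_mean(rm.reho_map(s, mask)))
        for s in series
    ]
    feats = rm.build_features(maps, mask)
    labels = np.array([r.group for r in records])
    return feats, labels, maps, mask


def naive_kcc(ts):
    """Independent loop-based Kendall's W (rank-sum formula), for oracles."""
    from scipy.stats import rankdata

    ts = np.asarray(ts, float)
    k, n = ts.shape
    ranks = np.array([rankdata(row) for row in ts])
    r = [sum(ranks[j][i] for j in range(k)) for i in range(n)]
    rbar = (n + 1) * k / 2.0
    num = sum(ri**2 for ri in r) - n * rbar**2
    den = (k * k * (n**3 - n)) / 12.0
    return num / den
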