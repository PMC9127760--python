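"""Feature assembly, linear classifiers, LOSOCV and performance metrics."""

import numpy as np
import pytest
from scipy.optimize import minimize

import rehomvpa as rm
from rehomvpa.gpc import LaplaceGPC
from rehomvpa.mvpa import FeatureMatrix, rank_auc


def _fm(values, ids=None):
    values = np.asarray(values, float)
    vox = np.array([(0, 0, j) for j in range(values.shape[1])])
    ids = ids or [f"s{i}" for i in range(values.shape[0])]
    return FeatureMatrix(values, vox, ids, grid_shape=(1, 1, values.shape[1]))


# ---------------------------------------------------------------- features

def test_build_features_shape_order_and_roundtrip(rng):
    mask = np.zeros((3, 3, 3), bool)
    coords = [(0, 0, 1), (0, 2, 0), (1, 1, 1), (2, 0, 0), (2, 2, 2)]
    for c in coords:
        mask[c] = True
    maps = []
    for s in range(3):
        vals = np.where(mask, rng.normal(size=(3, 3, 3)), 0.0)
        maps.append(rm.ReHoMap(vals, mask, stage="smoothed", subject_id=f"s{s}"))
    feats = rm.build_features(maps, mask)
    assert feats.values.shape == (3, 5)
    # lexicographically first in-mask coordinate maps to column 0
    assert tuple(feats.voxel_index[0]) == (0, 0, 1)
    back = rm.features_to_map(feats.values[1], feats.voxel_index, (3, 3, 3))
    assert np.array_equal(back, maps[1].values)


def test_grid_mismatch_raises(rng):
    mask = np.ones((3, 3, 3), bool)
    bad = rm.ReHoMap(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool), stage="smoothed")
    with pytest.raises(ValueError, match="grid"):
        rm.build_features([bad], mask)


def test_mean_center_uses_training_statistics_only():
    train = _fm([[1.0, 0.0], [3.0, 0.0]])
    test = _fm([[2.0, 5.0]], ids=["t"])
    ctrain, ctest = rm.mean_center(train, test)
    assert np.allclose(ctrain.values[:, 0], [-1.0, 1.0])
    assert ctest.values[0, 0] == pytest.approx(0.0)
    assert ctest.values[0, 1] == pytest.approx(5.0)  # test stats never used
    assert np.abs(ctrain.values.mean(0)).max() < 1e-12

    single = _fm([[4.0, 2.0]])
    a, b = rm.mean_center(single, single)
    assert np.all(a.values == 0) and np.all(b.values == 0)


# --------------------------------------------------------------------- SVM

def test_svm_symmetric_separable_pair():
    x = np.array([[-1.0], [1.0]])
    y = np.array(["a", "b"])
    model = rm.fit_linear_svm(x, y)
    assert list(model.predict(x)) == ["a", "b"]
    assert abs(model.bias) < 1e-6


def _hinge_objective(w, b, x, y_signed, c):
    margins = 1 - y_signed * (x @ w + b)
    return 0.5 * w @ w + c * np.maximum(0, margins).sum()


def test_svm_hinge_objective_matches_convex_solver(rng):
    # non-separable 1-D data (XOR-like interleaving)
    x = np.array([[-2.0], [-1.0], [1.0], [2.0], [-0.5], [0.5]])
    y = np.array(["a", "b", "a", "b", "b", "a"])
    y_signed = np.where(y == "b", 1.0, -1.0)
    c = 1.0
    model = rm.fit_linear_svm(x, y, c_param=c)
    obj_svm = _hinge_objective(model.weights, model.bias, x, y_signed, c)

    def f(params):
        return _hinge_objective(params[:1], params[1], x, y_signed, c)

    best = min(
        (minimize(f, x0, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12})
         for x0 in ([0.0, 0.0], [1.0, 0.0], [-1.0, 0.5])),
        key=lambda r: r.fun,
    )
    assert obj_svm == pytest.approx(best.fun, abs=1e-3)


def test_duplicated_feature_column_splits_weight(rng):
    """Duplicating a column is equivalent to scaling it by sqrt(2): the two
    copies share the weight equally and their sum matches the scaled fit."""
    x = rng.normal(size=(20, 3))
    y = np.where(x[:, 0] + 0.3 * rng.normal(size=20) > 0, "p", "n")
    if len(np.unique(y)) < 2:
        pytest.skip("degenerate draw")
    xdup = np.column_stack([x, x[:, 0]])
    m2 = rm.fit_linear_svm(xdup, y)
    assert m2.weights[0] == pytest.approx(m2.weights[3], abs=1e-8)
    xscaled = x.copy()
    xscaled[:, 0] *= np.sqrt(2.0)
    m3 = rm.fit_linear_svm(xscaled, y)
    assert m2.weights[0] + m2.weights[3] == pytest.approx(
        np.sqrt(2.0) * m3.weights[0], abs=1e-6
    )
    assert np.allclose(m2.weights[1:3], m3.weights[1:3], atol=1e-6)


def test_single_class_training_raises():
    with pytest.raises(ValueError):
        rm.fit_linear_svm(np.zeros((3, 2)), np.array(["a", "a", "a"]))


# --------------------------------------------------------------------- GPC

def test_gpc_separated_clusters_confident(rng):
    x = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
    y = np.repeat(["a", "b"], 20)
    model = rm.fit_gpc(x, y, mode="binary")
    p = model.predict_proba(np.array([[3.0, 3.0]]))
    assert p[0, 1] > 0.9
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-8)


def test_gpc_prior_collapse_on_zero_features():
    y = np.array(["a"] * 40 + ["b"] * 20)
    model = rm.fit_gpc(np.zeros((60, 4)), y, mode="binary")
    p = model.predict_proba(np.zeros((1, 4)))[0]
    assert p[1] == pytest.approx(20 / 60, abs=0.02)

    ym = np.array(["a"] * 30 + ["b"] * 18 + ["c"] * 12)
    mm = rm.fit_gpc(np.zeros((60, 4)), ym, mode="multiclass")
    pm = mm.predict_proba(np.zeros((1, 4)))[0]
    assert np.allclose(pm, [0.5, 0.3, 0.2], atol=0.02)
    assert pm.sum() == pytest.approx(1.0, abs=1e-8)


def test_gpc_binary_agrees_with_sklearn_reference(rng):
    """Cross-check the Laplace fit against an independent implementation."""
    from sklearn.gaussian_process import GaussianProcessClassifier
    from sklearn.gaussian_process.kernels import DotProduct

    x = np.vstack([rng.normal(-1.5, 0.8, (25, 2)), rng.normal(1.5, 0.8, (25, 2))])
    y = np.repeat([0, 1], 25)
    ours = LaplaceGPC(sigma0_sq=1.0).fit(x, y)
    ref = GaussianProcessClassifier(
        kernel=DotProduct(sigma_0=1.0, sigma_0_bounds="fixed"), optimizer=None
    ).fit(x, y)
    grid = rng.normal(0, 2, (40, 2))
    p_ours = ours.predict_proba(grid)[:, 1]
    p_ref = ref.predict_proba(grid)[:, 1]
    # same posterior family, different predictive approximations: demand
    # agreement of the decisions and closeness of the probabilities
    assert np.mean((p_ours > 0.5) == (p_ref > 0.5)) >= 0.95
    assert np.corrcoef(p_ours, p_ref)[0, 1] > 0.95


def test_mgpc_three_class_simplex_losocv(rng):
    means = np.array([[0, 0], [4, 0], [0, 4]])
    x = np.vstack([rng.normal(m, 0.5, (12, 2)) for m in means])
    y = np.repeat(["a", "b", "c"], 12)
    vox = np.array([(0, 0, 0), (0, 0, 1)])
    feats = FeatureMatrix(x, vox, [f"s{i}" for i in range(36)])
    res = rm.losocv(feats, y, algorithm="mgpc")
    assert res.metrics["total_accuracy"] > 0.9


def test_mgpc_with_two_classes_degrades_to_binary(rng):
    x = np.vstack([rng.normal(-2, 0.5, (10, 2)), rng.normal(2, 0.5, (10, 2))])
    y = np.repeat(["a", "b"], 10)
    model = rm.fit_gpc(x, y, mode="multiclass")
    proba = model.predict_proba(x)
    assert proba.shape == (20, 2)
    assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-8)


def test_gpc_nonconvergence_reports_iterations():
    from rehomvpa.gpc import GPCNotConverged

    g = LaplaceGPC(max_iter=1)
    with pytest.raises(GPCNotConverged, match="iteration"):
        g.fit(np.random.default_rng(0).normal(size=(20, 2)), np.repeat([0, 1], 10))


# ------------------------------------------------------------------ LOSOCV

def test_losocv_perfect_separation_and_fold_contract(small_cohort_features):
    feats, labels, _, _ = small_cohort_features
    res = rm.losocv(feats, labels, algorithm="svm")
    assert res.metrics["total_accuracy"] == 1.0
    assert len(res.y_pred) == feats.n_subjects  # one prediction per subject
    assert res.confusion.sum() == feats.n_subjects
    # deterministic: bit-identical rerun
    res2 = rm.losocv(feats, labels, algorithm="svm")
    assert np.array_equal(res.scores, res2.scores)
    assert np.array_equal(res.fold_weights, res2.fold_weights)


def test_losocv_shuffled_labels_near_chance(small_cohort_features, rng):
    feats, labels, _, _ = small_cohort_features
    shuffled = rng.permutation(labels)
    res = rm.losocv(feats, shuffled, algorithm="svm")
    n = feats.n_subjects
    from scipy.stats import binom

    lo, hi = binom.ppf([0.005, 0.995], n, 0.5) / n
    assert lo <= res.metrics["total_accuracy"] <= hi


def test_losocv_centering_has_no_test_leakage():
    """Fold-0 training is identical whatever the held-out subject looks like."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=(10, 4))
    y = np.array(["a", "b"] * 5)
    xa, xb = x.copy(), x.copy()
    xa[0] += 50.0  # extreme held-out subject in fold 0
    xb[0] -= 50.0
    res_a = rm.losocv(_fm(xa), y, algorithm="svm")
    res_b = rm.losocv(_fm(xb), y, algorithm="svm")
    # the held-out row never enters fold 0's centering or fit
    assert np.array_equal(res_a.fold_weights[0], res_b.fold_weights[0])
    # but it does influence the folds where it is a training subject
    assert not np.array_equal(res_a.fold_weights[1], res_b.fold_weights[1])


def test_losocv_single_class_fold_raises():
    x = np.random.default_rng(0).normal(size=(4, 2))
    y = np.array(["a", "a", "a", "b"])  # removing the lone 'b' breaks a fold
    feats = _fm(x)
    with pytest.raises(ValueError, match="single class"):
        rm.losocv(feats, y)


def test_weight_pullback_localizes_effect(small_cohort_features):
    feats, labels, _, mask = small_cohort_features
    res = rm.losocv(feats, labels, algorithm="svm")
    w_map = rm.features_to_map(np.abs(res.mean_weights), feats.voxel_index, mask.shape)
    truth = np.zeros(mask.shape, bool)
    truth[3:9, 3:9, 3:9] = True
    top = w_map >= np.quantile(w_map[mask], 1 - truth.sum() / mask.sum())
    dice = 2 * (top & truth).sum() / (top.sum() + truth.sum())
    assert dice > 0.5


# ----------------------------------------------------------------- metrics

def test_sensitivity_arithmetic_33_of_41():
    confusion = np.array([[33, 8], [4, 41]])
    m = rm.performance_metrics(confusion, classes=np.array(["DET", "HC"]), positive="DET")
    assert round(100 * m["sensitivity"], 2) == 80.49
    assert m["specificity"] == pytest.approx(41 / 45)
    assert m["ppv"] == pytest.approx(33 / 37)
    assert m["npv"] == pytest.approx(41 / 49)
    assert m["balanced_accuracy"] == pytest.approx((33 / 41 + 41 / 45) / 2)


def test_identity_confusion_all_metrics_one():
    m = rm.performance_metrics(np.diag([10, 12]), classes=np.array(["a", "b"]))
    for key in ("total_accuracy", "sensitivity", "specificity", "ppv", "npv"):
        assert m[key] == 1.0


def test_zero_denominator_metric_is_nan_with_warning():
    confusion = np.array([[0, 0], [3, 7]])  # no true positives at all
    with pytest.warns(UserWarning, match="sensitivity"):
        m = rm.performance_metrics(confusion, classes=np.array(["p", "n"]), positive="p")
    assert np.isnan(m["sensitivity"])


def test_auc_matches_pair_counting_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(6, 40))
        y = rng.choice(["p", "n"], size=n)
        if len(np.unique(y)) < 2:
            continue
        scores = rng.normal(size=n)
        scores[rng.random(n) < 0.2] = 0.0  # force ties
        auc = rank_auc(y, scores, "p")
        pos = scores[y == "p"]
        neg = scores[y == "n"]
        pairs = sum(
            1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg
        )
        assert auc == pytest.approx(pairs / (len(pos) * len(neg)), abs=1e-12)


def test_multiclass_metrics_per_class():
    confusion = np.array([[8, 1, 1], [2, 7, 1], [0, 0, 10]])
    m = rm.performance_metrics(confusion, classes=np.array(["DET", "ET", "HC"]))
    assert m["per_class_sensitivity"]["HC"] == 1.0
    assert m["total_accuracy"] == pytest.approx(25 / 30)
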