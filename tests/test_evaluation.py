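"""Confusion counting, the per-class metric formulas, k-fold machinery and
class-area accounting."""

import numpy as np
import pytest

from mosshealth.evaluation import (
    ConfusionMatrix,
    confusion,
    metrics,
    kfold,
    area_report,
)


def brute_force_confusion(truth, pred, n=5):
    cm = np.zeros((n, n), dtype=int)
    for t, p in zip(truth.ravel(), pred.ravel()):
        if t > 0 and 1 <= p <= n:
            cm[t - 1, p - 1] += 1
    return cm


def test_perfect_prediction_is_diagonal():
    rng = np.random.default_rng(0)
    t = rng.integers(1, 6, (20, 20))
    cm = confusion(t, t)
    assert (cm.counts == np.diag(np.diag(cm.counts))).all()
    rep = metrics(cm)
    np.testing.assert_allclose(rep.precision, 1.0)
    np.testing.assert_allclose(rep.recall, 1.0)
    np.testing.assert_allclose(rep.f1, 1.0)
    np.testing.assert_allclose(rep.iou, 1.0)


def test_single_cell_confusion():
    t = np.ones((5, 5), dtype=int)
    p = np.full((5, 5), 2)
    cm = confusion(t, p)
    assert cm.counts[0, 1] == 25
    assert cm.counts.sum() == 25


def test_confusion_matches_brute_force_counting():
    rng = np.random.default_rng(9)
    t = rng.integers(0, 6, (50, 50))
    p = rng.integers(0, 6, (50, 50))
    cm = confusion(t, p)
    np.testing.assert_array_equal(cm.counts, brute_force_confusion(t, p))


def test_truth_zero_excluded_and_shape_mismatch_raises():
    t = np.zeros((4, 4), dtype=int)
    p = np.ones((4, 4), dtype=int)
    assert confusion(t, p).n == 0
    with pytest.raises(ValueError, match="mismatch"):
        confusion(np.zeros((3, 3)), np.zeros((4, 4)))


def test_hand_evaluated_metrics():
    # TP=8, FP=2, FN=2 for class 1
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 8
    counts[0, 1] = 2  # FN of class 1
    counts[1, 0] = 2  # FP of class 1
    rep = metrics(ConfusionMatrix(counts=counts, class_ids=tuple(range(1, 6))))
    assert rep.precision[0] == pytest.approx(0.8)
    assert rep.recall[0] == pytest.approx(0.8)
    assert rep.f1[0] == pytest.approx(0.8)
    assert rep.iou[0] == pytest.approx(8 / 12)


def _random_confusions(n_mat, rng):
    for _ in range(n_mat):
        yield ConfusionMatrix(
            counts=rng.integers(0, 50, (5, 5)), class_ids=tuple(range(1, 6))
        )


def test_f1_is_harmonic_mean_identity():
    """The printed F1 form 2TP/(FP+2TP+FN) equals 2PR/(P+R)."""
    rng = np.random.default_rng(21)
    for cm in _random_confusions(1000, rng):
        rep = metrics(cm)
        p, r = rep.precision, rep.recall
        ok = (p + r) > 0
        np.testing.assert_allclose(
            rep.f1[ok], 2 * p[ok] * r[ok] / (p[ok] + r[ok]), atol=1e-12
        )


def test_micro_precision_equals_accuracy():
    rng = np.random.default_rng(22)
    for cm in _random_confusions(200, rng):
        rep = metrics(cm)
        tp, fp = cm.tp().sum(), cm.fp().sum()
        if tp + fp:
            assert tp / (tp + fp) == pytest.approx(rep.accuracy, abs=1e-12)


def test_metrics_against_brute_force_counts():
    rng = np.random.default_rng(23)
    for cm in _random_confusions(100, rng):
        rep = metrics(cm)
        for i in range(5):
            tp = cm.counts[i, i]
            fp = cm.counts[:, i].sum() - tp
            fn = cm.counts[i, :].sum() - tp
            if tp + fp:
                assert rep.precision[i] == pytest.approx(tp / (tp + fp), abs=1e-12)
            if tp + fn:
                assert rep.recall[i] == pytest.approx(tp / (tp + fn), abs=1e-12)
            if tp + fp + fn:
                assert rep.iou[i] == pytest.approx(tp / (tp + fp + fn), abs=1e-12)


def test_zero_support_class_flagged_not_nan():
    counts = np.zeros((5, 5), dtype=int)
    counts[0, 0] = 10
    rep = metrics(ConfusionMatrix(counts=counts, class_ids=tuple(range(1, 6))))
    assert np.isfinite(rep.f1).all()
    assert rep.f1[4] == 0.0
    assert rep.undefined[4]
    assert not rep.undefined[0]


def test_relabel_permutation_invariance():
    rng = np.random.default_rng(31)
    t = rng.integers(1, 6, (40, 40))
    p = rng.integers(1, 6, (40, 40))
    rep = metrics(confusion(t, p))
    perm = np.array([0, 3, 1, 4, 2, 5])  # class i -> perm[i]
    rep2 = metrics(confusion(perm[t], perm[p]))
    inv = np.argsort(perm[1:])  # position of old class i in the new ordering
    np.testing.assert_allclose(rep2.f1[perm[1:] - 1], rep.f1)
    np.testing.assert_allclose(rep2.iou[perm[1:] - 1], rep.iou)


def test_row_normalized_rows_sum_to_one():
    rng = np.random.default_rng(32)
    cm = confusion(rng.integers(1, 6, (30, 30)), rng.integers(1, 6, (30, 30)))
    norm = cm.normalized()
    rows = cm.counts.sum(axis=1) > 0
    np.testing.assert_allclose(norm[rows].sum(axis=1), 1.0, atol=1e-12)


# --- k-fold -----------------------------------------------------------------


def _nearest_mean_trainer(X_tr, y_tr, X_te, y_te):
    classes = np.unique(y_tr)
    mus = np.stack([X_tr[y_tr == c].mean(axis=0) for c in classes])
    d = ((X_te[:, None, :] - mus[None]) ** 2).sum(-1)
    pred = classes[d.argmin(axis=1)]
    return float((pred == y_te).mean()), None


def test_kfold_mean_std_equal_manual_aggregation():
    rng = np.random.default_rng(41)
    X = rng.normal(size=(300, 4))
    y = rng.integers(1, 4, 300)
    res = kfold(X, y, k=5, trainer=_nearest_mean_trainer, seed=3)
    assert res.mean_accuracy == pytest.approx(np.mean(res.fold_accuracy))
    assert res.std_accuracy == pytest.approx(np.std(res.fold_accuracy))
    assert min(res.fold_accuracy) <= res.mean_accuracy <= max(res.fold_accuracy)


def test_identical_folds_give_zero_std():
    def constant_trainer(X_tr, y_tr, X_te, y_te):
        return 0.75, None

    rng = np.random.default_rng(42)
    res = kfold(rng.normal(size=(100, 2)), rng.integers(1, 3, 100), k=4,
                trainer=constant_trainer, seed=0)
    assert res.std_accuracy == 0.0


def test_kfold_separable_data_high_accuracy():
    rng = np.random.default_rng(43)
    y = rng.integers(1, 6, 500)
    X = np.eye(6)[y] * 10 + rng.normal(size=(500, 6))
    res = kfold(X, y, k=10, trainer=_nearest_mean_trainer, seed=1)
    assert res.mean_accuracy >= 0.95


def test_kfold_tile_unit_keeps_groups_together():
    captured = []

    def spy_trainer(X_tr, y_tr, X_te, y_te):
        captured.append((X_tr[:, 0], X_te[:, 0]))
        return 1.0, None

    groups = np.repeat(np.arange(10), 20)
    X = groups[:, None].astype(float)
    y = np.tile(np.arange(1, 3), 100)
    kfold(X, y, k=5, trainer=spy_trainer, fold_unit="tile", groups=groups, seed=0)
    for tr, te in captured:
        assert not set(np.unique(tr)) & set(np.unique(te))


def test_kfold_validation_errors():
    X, y = np.zeros((10, 2)), np.tile([1, 2], 5)
    with pytest.raises(ValueError, match="k"):
        kfold(X, y, k=1, trainer=_nearest_mean_trainer)
    with pytest.raises(ValueError, match="k"):
        kfold(X, y, k=11, trainer=_nearest_mean_trainer)
    with pytest.raises(ValueError, match="groups"):
        kfold(X, y, k=2, trainer=_nearest_mean_trainer, fold_unit="tile")


# --- areas ------------------------------------------------------------------


def test_single_class_map_is_100_percent():
    rep = area_report(np.full((10, 10), 3), pixel_area=0.5)
    assert rep["classes"][3]["percent"] == pytest.approx(100.0)
    assert rep["classes"][3]["area_m2"] == pytest.approx(50.0)


def test_area_arithmetic_at_ground_sampling_distance():
    # 3.2 cm GSD -> 0.032**2 = 0.001024 m^2/pixel; 1000 lichen pixels -> 1.024 m^2
    seg = np.zeros((40, 40), dtype=int)
    seg.ravel()[:1000] = 4
    rep = area_report(seg, pixel_area=0.032**2)
    assert rep["classes"][4]["area_m2"] == pytest.approx(1.024)


def test_percentages_sum_to_100_over_labeled():
    rng = np.random.default_rng(55)
    seg = rng.integers(0, 6, (64, 64))
    rep = area_report(seg, pixel_area=0.001024)
    total = sum(rep["classes"][c]["percent"] for c in range(1, 6))
    assert total == pytest.approx(100.0, abs=1e-9)


def test_area_errors():
    with pytest.raises(ValueError, match="pixel_area"):
        area_report(np.ones((4, 4), int), pixel_area=0.0)
    with pytest.raises(ValueError, match="region"):
        area_report(np.ones((4, 4), int), pixel_area=1.0, region=np.zeros((4, 4), bool))
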