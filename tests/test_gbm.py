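"""Stage-1 classifier: feature tables, training, importance, tiled inference."""

import numpy as np
import pytest

from mosshealth import synthetic
from mosshealth.bands import BandStack
from mosshealth.features import FeatureSpec
from mosshealth.evaluation import evaluate
from mosshealth.gbm import (
    GbmConfig,
    build_feature_table,
    train_gbm,
    predict_gbm,
    predict_rows,
    save_model,
    load_model,
)

FAST_SPEC = FeatureSpec(indices=("NDVI", "GNDVI", "NDRE"), stats_bands=())
FAST_CFG = GbmConfig(n_estimators=60, max_depth=6, learning_rate=0.2, seed=0)


@pytest.fixture(scope="module")
def scene():
    return synthetic.generate(synthetic.default_spec("easy", height=128, width=128, seed=17))


@pytest.fixture(scope="module")
def fitted(scene):
    rows, y, _, names = build_feature_table(scene.stack, FAST_SPEC, labels=scene.sparse_labels)
    return train_gbm(rows, y, FAST_CFG, spec=FAST_SPEC, feature_names=names)


def test_feature_table_row_counts(rng):
    stack = BandStack.from_array(rng.uniform(0.05, 0.95, (6, 10, 10)))
    labels = np.ones((10, 10), dtype=int)
    rows, y, _, names = build_feature_table(stack, FAST_SPEC, labels=labels)
    assert rows.shape == (100, 9)  # 6 bands + 3 indices
    assert len(names) == 9

    sparse = np.zeros((10, 10), dtype=int)
    idx = rng.choice(100, size=37, replace=False)
    sparse.ravel()[idx] = rng.integers(1, 6, 37)
    rows, y, _, _ = build_feature_table(stack, FAST_SPEC, labels=sparse)
    assert rows.shape[0] == 37 == len(y)


def test_feature_table_errors(rng):
    stack = BandStack.from_array(rng.uniform(0.05, 0.95, (6, 8, 8)))
    with pytest.raises(KeyError, match="unknown"):
        build_feature_table(stack, FeatureSpec(indices=("BOGUS",)))
    stack.nodata_mask[:] = True
    with pytest.raises(ValueError, match="no valid"):
        build_feature_table(stack, FAST_SPEC)


def test_separable_classes_train_to_perfect_accuracy(rng):
    y = rng.integers(1, 3, 400)
    X = np.zeros((400, 3))
    X[:, 0] = y * 10.0  # perfectly separating feature
    X[:, 1:] = rng.normal(size=(400, 2))
    model = train_gbm(X, y, FAST_CFG, feature_names=["sep", "n1", "n2"])
    pred = predict_rows(model, X).argmax(axis=1) + 1
    assert (pred == y).all()
    # the label-carrying feature dominates the gain ranking
    assert model.importance().index[0] == "sep"


def test_shuffled_labels_give_chance_accuracy(rng):
    n = 10_000
    X = rng.normal(size=(n, 5))
    y = np.tile(np.arange(1, 6), n // 5)  # balanced, independent of X
    cfg = GbmConfig(n_estimators=30, max_depth=4, seed=1)
    model = train_gbm(X[: n // 2], y[: n // 2], cfg, feature_names=list("abcde"))
    pred = predict_rows(model, X[n // 2 :]).argmax(axis=1) + 1
    acc = (pred == y[n // 2 :]).mean()
    assert abs(acc - 0.2) < 0.05


def test_single_class_labels_rejected(rng):
    with pytest.raises(ValueError, match="2 classes"):
        train_gbm(rng.normal(size=(50, 3)), np.ones(50, dtype=int))


def test_probabilities_sum_to_one(fitted, scene):
    _, soft = predict_gbm(fitted, scene.stack)
    valid = soft.sum(axis=0) > 0
    np.testing.assert_allclose(soft.sum(axis=0)[valid], 1.0, atol=1e-6)
    assert soft.shape[0] == 5


def test_training_raster_reproduced_on_labeled_pixels(scene, fitted):
    hard, _ = predict_gbm(fitted, scene.stack)
    nz = scene.sparse_labels > 0
    agree = (hard[nz] == scene.sparse_labels[nz]).mean()
    assert agree > 0.99


def test_tiled_vs_untiled_prediction_identical(scene, fitted):
    hard_small, soft_small = predict_gbm(fitted, scene.stack, tile=50)
    hard_full, soft_full = predict_gbm(fitted, scene.stack, tile=10_000)
    np.testing.assert_array_equal(hard_small, hard_full)
    np.testing.assert_allclose(soft_small, soft_full, atol=1e-12)


def test_determinism_same_seed_same_predictions(scene):
    rows, y, _, names = build_feature_table(scene.stack, FAST_SPEC, labels=scene.sparse_labels)
    m1 = train_gbm(rows, y, FAST_CFG, spec=FAST_SPEC, feature_names=names)
    m2 = train_gbm(rows, y, FAST_CFG, spec=FAST_SPEC, feature_names=names)
    np.testing.assert_array_equal(predict_rows(m1, rows), predict_rows(m2, rows))


def test_model_round_trip(tmp_path, fitted, scene):
    path = tmp_path / "model.json"
    save_model(fitted, path)
    loaded = load_model(path)
    assert loaded.feature_names == fitted.feature_names
    assert loaded.config == fitted.config
    h1, s1 = predict_gbm(fitted, scene.stack)
    h2, s2 = predict_gbm(loaded, scene.stack)
    np.testing.assert_array_equal(h1, h2)


def test_feature_spec_mismatch_raises(scene, fitted):
    import dataclasses

    other = synthetic.generate(synthetic.default_spec("easy", height=64, width=64, seed=1))

    wrong = dataclasses.replace(fitted, feature_names=["x", "y"])
    with pytest.raises(ValueError, match="feature spec mismatch"):
        predict_gbm(wrong, other.stack)


def test_easy_scene_heldout_macro_f1(scene, fitted):
    hard, _ = predict_gbm(fitted, scene.stack)
    heldout = np.where(scene.sparse_labels > 0, 0, scene.truth)
    rep = evaluate(heldout, hard)
    assert rep.macro_f1 >= 0.95
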