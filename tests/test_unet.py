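"""Encoder-decoder segmenter: shapes, determinism, optimization behavior."""

import numpy as np
import pytest

from mosshealth import synthetic
from mosshealth.unet import (
    CnnConfig,
    build_network,
    make_patches,
    train_cnn,
    run_method,
    save_checkpoint,
    load_checkpoint,
    UNetModel,
)
from mosshealth import nn

TINY = CnnConfig(
    patch_size=32,
    ladder=(4, 8, 16, 32),
    bottleneck=64,
    epochs=4,
    batch_size=4,
    learning_rate=0.002,
    seed=0,
)


def test_output_shape_contract():
    net = build_network(TINY, in_channels=6)
    x = np.zeros((2, 6, 32, 32), dtype=np.float32)
    logits = net.forward(x, train=False)
    assert logits.shape == (2, 5, 32, 32)


def test_parameter_count_grows_with_ladder():
    small = build_network(TINY, in_channels=6)
    big = build_network(
        CnnConfig(patch_size=32, ladder=(16, 32, 64, 128), bottleneck=256, seed=0),
        in_channels=6,
    )
    assert big.n_params() > small.n_params()


def test_scaled_preset_shrinks_defaults():
    full = CnnConfig()
    small = full.scaled("small")
    assert small.ladder == (16, 32, 64, 128) and small.bottleneck == 256
    assert small.epochs <= 50
    assert full.ladder == (64, 128, 256, 512) and full.bottleneck == 1024


def test_indivisible_patch_rejected():
    with pytest.raises(ValueError, match="divisible"):
        build_network(CnnConfig(patch_size=100), in_channels=6)
    net = build_network(TINY, in_channels=6)
    with pytest.raises(ValueError, match="divisible"):
        net.forward(np.zeros((1, 6, 30, 30), dtype=np.float32))


def test_eval_forward_deterministic():
    net = build_network(TINY, in_channels=6)
    rng = np.random.default_rng(0)
    x = rng.normal(size=(1, 6, 32, 32)).astype(np.float32)
    a = net.forward(x, train=False)
    b = net.forward(x, train=False)
    np.testing.assert_array_equal(a, b)


def test_patch_grid_enumeration_matches_tiling():
    rng = np.random.default_rng(1)
    channels = rng.uniform(size=(6, 256, 256))
    labels = np.ones((256, 256), dtype=int)
    cfg = CnnConfig(patch_size=128, patch_overlap=0.3, seed=0)
    patches, labs, windows = make_patches(channels, labels, cfg)
    assert len(patches) == 9  # origins {0, 89, 128} in each axis


def test_unlabeled_patches_dropped():
    rng = np.random.default_rng(2)
    channels = rng.uniform(size=(6, 64, 64))
    labels = np.zeros((64, 64), dtype=int)
    labels[:32, :32] = 3  # only the top-left patch is labeled
    cfg = CnnConfig(patch_size=32, patch_overlap=0.0, seed=0)
    patches, labs, windows = make_patches(channels, labels, cfg)
    assert windows == [(0, 0, 32, 32)]
    with pytest.raises(ValueError, match="labeled"):
        make_patches(channels, np.zeros((64, 64), dtype=int), cfg)


def test_raster_smaller_than_patch_rejected():
    with pytest.raises(ValueError, match="smaller than patch"):
        make_patches(np.zeros((6, 16, 16)), np.ones((16, 16), int), TINY)


def test_no_filter_patches_equal_source_crops():
    rng = np.random.default_rng(3)
    channels = rng.uniform(size=(6, 64, 64))
    labels = np.ones((64, 64), dtype=int)
    cfg = CnnConfig(patch_size=32, patch_overlap=0.0, input_filter=None, seed=0)
    patches, _, windows = make_patches(channels, labels, cfg)
    for patch, (r, c, h, w) in zip(patches, windows):
        np.testing.assert_array_equal(patch, channels[:, r : r + h, c : c + w])


def test_input_filters_smooth():
    rng = np.random.default_rng(4)
    channels = rng.uniform(size=(6, 64, 64))
    labels = np.ones((64, 64), dtype=int)
    for kind in ("lowpass", "gaussian"):
        cfg = CnnConfig(patch_size=32, input_filter=(kind, 5), seed=0)
        patches, _, _ = make_patches(channels, labels, cfg)
        assert patches.std() < channels.std()
    with pytest.raises(ValueError, match="filter"):
        make_patches(channels, labels, CnnConfig(patch_size=32, input_filter=("lowpass", 4)))


@pytest.fixture(scope="module")
def tiny_scene():
    return synthetic.generate(synthetic.default_spec("easy", height=96, width=96, seed=12))


@pytest.fixture(scope="module")
def trained(tiny_scene):
    cfg = CnnConfig(
        patch_size=32, ladder=(4, 8, 16, 32), bottleneck=64,
        epochs=12, batch_size=8, learning_rate=0.003, seed=5,
    )
    patches, labs, _ = make_patches(tiny_scene.stack.as_array(), tiny_scene.sparse_labels, cfg)
    model, log = train_cnn(patches, labs, cfg)
    return model, log


def test_training_loss_descends(trained):
    _, log = trained
    losses = [e["train_loss"] for e in log.epochs]
    assert losses[-1] < losses[0]
    # averaged late-window loss below early-window loss
    assert np.mean(losses[-3:]) < np.mean(losses[:3])


def test_training_deterministic(tiny_scene):
    cfg = CnnConfig(patch_size=32, ladder=(4, 8), bottleneck=16, epochs=2,
                    batch_size=4, seed=7)
    # 2-level ladder is rejected; use the 4-level tiny config twice instead
    cfg = CnnConfig(patch_size=32, ladder=(4, 8, 16, 32), bottleneck=64, epochs=2,
                    batch_size=4, seed=7)
    patches, labs, _ = make_patches(tiny_scene.stack.as_array(), tiny_scene.sparse_labels, cfg)
    m1, l1 = train_cnn(patches, labs, cfg)
    m2, l2 = train_cnn(patches, labs, cfg)
    assert l1.epochs == l2.epochs
    p1 = m1.predict_proba_patches(patches[:2])
    p2 = m2.predict_proba_patches(patches[:2])
    np.testing.assert_array_equal(p1, p2)


def test_one_class_labels_converge_to_that_class(tiny_scene):
    cfg = CnnConfig(patch_size=32, ladder=(4, 8, 16, 32), bottleneck=64, epochs=25,
                    batch_size=2, learning_rate=0.003, dropout=0.0,
                    test_fraction=0.0, seed=3)
    channels = tiny_scene.stack.as_array()
    labels = np.full(tiny_scene.truth.shape, 2)
    patches, labs, _ = make_patches(channels, labels, cfg)
    model, log = train_cnn(patches[:6], labs[:6], cfg)
    assert log.last()["train_acc"] == 1.0
    probs = model.predict_proba_patches(patches[:2])
    assert (probs.argmax(axis=1) == 1).all()


def test_checkpoint_round_trip(tmp_path, trained, tiny_scene):
    model, _ = trained
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    loaded = load_checkpoint(path)
    assert loaded.cfg == model.cfg
    channels = tiny_scene.stack.as_array()
    h1, s1 = model.segment(channels)
    h2, s2 = loaded.segment(channels)
    np.testing.assert_array_equal(h1, h2)
    np.testing.assert_allclose(s1, s2, atol=1e-7)


def test_segment_outputs_valid_ids_and_probs(trained, tiny_scene):
    model, _ = trained
    hard, soft = model.segment(tiny_scene.stack.as_array())
    assert set(np.unique(hard)) <= set(range(1, 6))
    np.testing.assert_allclose(soft.sum(axis=0), 1.0, atol=1e-6)


def test_method_channel_counts_and_errors(tiny_scene):
    cfg = CnnConfig(patch_size=32, ladder=(4, 8, 16, 32), bottleneck=64, epochs=1,
                    batch_size=8, seed=1)
    with pytest.raises(ValueError, match="stage-1"):
        run_method(2, tiny_scene.stack, tiny_scene.sparse_labels, cfg)
    with pytest.raises(ValueError, match="method"):
        run_method(3, tiny_scene.stack, tiny_scene.sparse_labels, cfg)
    uniform = np.full((5,) + tiny_scene.truth.shape, 0.2)
    _, _, model, _ = run_method(
        2, tiny_scene.stack, tiny_scene.sparse_labels, cfg, stage1_probs=uniform
    )
    assert model.in_channels == 11
    _, _, model1, _ = run_method(1, tiny_scene.stack, tiny_scene.sparse_labels, cfg)
    assert model1.in_channels == 6


def test_masked_cross_entropy_ignores_unlabeled():
    rng = np.random.default_rng(8)
    logits = rng.normal(size=(1, 5, 8, 8))
    labels = rng.integers(1, 6, (1, 8, 8))
    l_full, _, g_full = nn.masked_cross_entropy(logits, labels)
    half = labels.copy()
    half[:, 4:] = 0
    l_half, _, g_half = nn.masked_cross_entropy(logits, half)
    assert (g_half[:, :, 4:] == 0).all()
    with pytest.raises(ValueError, match="labeled"):
        nn.masked_cross_entropy(logits, np.zeros((1, 8, 8), int))
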