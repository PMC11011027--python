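"""Serial network assembly, loss closed forms, optimiser schedule, training."""

import numpy as np
import pytest

from tigerreid import (ReIDModel, SerialReIDNet, TrainConfig, cross_entropy,
                       lr_at_epoch, make_dataset, make_optimizer)
from tigerreid import autograd as ag
from tigerreid.autograd import Tensor
from tigerreid.reid_net import normalize_images, set_epoch_lr


def _images(n, seed=0):
    return np.random.default_rng(seed).uniform(size=(n, 64, 128, 3)).astype(np.float32)


# ---------------------------------------------------------------------------
# cross-entropy closed forms
# ---------------------------------------------------------------------------

def test_cross_entropy_uniform_is_log_k():
    p = np.full(4, 0.25)
    y = np.array([0, 0, 1, 0], dtype=float)
    assert cross_entropy(p, y) == pytest.approx(np.log(4), rel=1e-9)


def test_cross_entropy_perfect_prediction_is_zero():
    p = np.array([0.0, 1.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    assert cross_entropy(p, y) == pytest.approx(0.0, abs=1e-9)


def test_cross_entropy_worked_three_class_case():
    p = np.array([0.7, 0.2, 0.1])
    y = np.array([1.0, 0.0, 0.0])
    assert cross_entropy(p, y) == pytest.approx(-np.log(0.7), rel=1e-6)
    assert cross_entropy(p, y) == pytest.approx(0.35667, abs=5e-6)


def test_cross_entropy_zero_probability_is_clamped():
    p = np.array([0.0, 1.0])
    y = np.array([1.0, 0.0])
    loss = cross_entropy(p, y)
    assert np.isfinite(loss) and loss > 20  # -log(1e-12)


def test_cross_entropy_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        cross_entropy(np.ones(3) / 3, np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# forward contracts
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def desk_net():
    net = SerialReIDNet(num_classes=5, profile="desk", seed=0)
    net.eval()
    return net


def test_descriptor_concatenation(desk_net):
    desc, out = desk_net.forward(normalize_images(_images(2)))
    assert desc.f_global.shape == (2, 256)
    assert desc.f_local.shape == (2, 256)
    assert desc.concat.shape == (2, 512)
    np.testing.assert_array_equal(
        desc.concat, np.concatenate([desc.f_global, desc.f_local], axis=1))
    assert out.logits.shape == (2, 5)
    np.testing.assert_allclose(out.probs.sum(axis=1), 1.0, atol=1e-6)


def test_identical_images_identical_descriptors(desk_net):
    img = _images(1, seed=3)
    batch = normalize_images(np.concatenate([img, img]))
    desc, _ = desk_net.forward(batch)
    np.testing.assert_array_equal(desc.concat[0], desc.concat[1])


@pytest.mark.parametrize("use_ifpm,use_laem,dim", [
    (False, False, 256),       # backbone only: pooled C4
    (True, False, 256),        # + global pyramid: F_Global
    (True, True, 512),         # + local branch: concat
])
def test_ablation_wiring_descriptor_dims(use_ifpm, use_laem, dim):
    net = SerialReIDNet(num_classes=3, profile="desk",
                        use_ifpm=use_ifpm, use_laem=use_laem, seed=0).eval()
    assert net.descriptor_dim == dim
    assert net.extract(normalize_images(_images(1))).shape == (1, dim)


def test_missing_class_count_rejected():
    with pytest.raises(ValueError, match="num_classes"):
        SerialReIDNet(num_classes=None, profile="desk")


def test_retrieval_feature_selection():
    net = SerialReIDNet(num_classes=3, profile="desk", feature="global",
                        seed=0).eval()
    assert net.extract(normalize_images(_images(1))).shape == (1, 256)
    with pytest.raises(ValueError, match="local"):
        SerialReIDNet(num_classes=3, profile="desk", use_laem=False,
                      feature="local")


# ---------------------------------------------------------------------------
# optimiser and schedule
# ---------------------------------------------------------------------------

def test_two_parameter_groups(desk_net):
    cfg = TrainConfig()
    opt = make_optimizer(cfg, desk_net)
    assert opt.param_groups[0]["lr"] == 0.002
    assert opt.param_groups[1]["lr"] == 0.02
    n_cls = len(desk_net.classifier.parameters())
    assert len(opt.param_groups[1]["params"]) == n_cls
    total = len(desk_net.parameters())
    assert len(opt.param_groups[0]["params"]) == total - n_cls


def test_learning_rate_schedule():
    cfg = TrainConfig()
    assert lr_at_epoch(cfg, 99) == (0.002, 0.02)
    assert lr_at_epoch(cfg, 100) == (pytest.approx(0.0002), pytest.approx(0.002))
    assert lr_at_epoch(cfg, 149) == (pytest.approx(0.0002), pytest.approx(0.002))


def test_constant_schedule_with_unit_factor():
    cfg = TrainConfig(lr_decay_factor=1.0)
    assert lr_at_epoch(cfg, 0) == lr_at_epoch(cfg, 120) == (0.002, 0.02)


def test_set_epoch_lr_updates_groups(desk_net):
    cfg = TrainConfig()
    opt = make_optimizer(cfg, desk_net)
    set_epoch_lr(opt, cfg, 100)
    assert opt.param_groups[0]["lr"] == pytest.approx(0.0002)
    assert opt.param_groups[1]["lr"] == pytest.approx(0.002)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(lr_base=-1.0)
    with pytest.raises(ValueError):
        TrainConfig(epochs=50)          # decay epoch no longer precedes end


def test_single_sgd_step_decreases_loss():
    """One small-lr step on one example strictly reduces that example's loss."""
    net = SerialReIDNet(num_classes=4, profile="desk", seed=2)
    net.eval()  # freeze BN statistics so the loss landscape is stationary
    x = Tensor(normalize_images(_images(1, seed=5)))
    y = np.array([2])
    cfg = TrainConfig(lr_base=0.0005, lr_classifier=0.0005, momentum=0.0,
                     weight_decay=0.0)
    opt = make_optimizer(cfg, net)
    _, logits = net.forward_tensors(x)
    before = ag.softmax_cross_entropy(logits, y)
    before.backward()
    opt.step()
    _, logits2 = net.forward_tensors(x)
    after = ag.softmax_cross_entropy(logits2, y)
    assert after.item() < before.item()


# ---------------------------------------------------------------------------
# training behaviour
# ---------------------------------------------------------------------------

def test_overfit_two_images_loss_decreases():
    imgs = _images(2, seed=7)
    model = ReIDModel(imgs, np.array([0, 1]), np.array(["train", "train"]),
                      config=TrainConfig(seed=0, batch_size=2, augment_prob=0.0),
                      profile="desk")
    res = model.fit(epochs=5)
    assert res.history["loss"].iloc[-1] < res.history["loss"].iloc[0]


def test_identical_images_distinct_labels_floor():
    """Indistinguishable inputs with different labels keep loss near ln K."""
    img = _images(1, seed=9)
    imgs = np.concatenate([img] * 4)
    model = ReIDModel(imgs, np.array([0, 1, 0, 1]), np.array(["train"] * 4),
                      config=TrainConfig(seed=0, batch_size=4, augment_prob=0.0),
                      profile="desk")
    res = model.fit(epochs=8)
    assert res.history["loss"].iloc[-1] >= np.log(2) - 0.05


def test_fit_history_and_summary(tiny_dataset):
    model = ReIDModel.from_dataset(tiny_dataset, config=TrainConfig(seed=3),
                                   profile="desk")
    res = model.fit(epochs=2)
    assert list(res.history["epoch"]) == [0, 1]
    assert np.isfinite(res.final_loss)
    assert 0.0 <= res.val_rank1 <= 1.0
    text = res.summary()
    assert "descriptor dim: 512" in text
    assert "val Rank-1" in text


def test_fit_reproducible_for_fixed_seed(tiny_dataset):
    runs = []
    for _ in range(2):
        model = ReIDModel.from_dataset(tiny_dataset, config=TrainConfig(seed=5),
                                       profile="desk")
        runs.append(model.fit(epochs=1).history["loss"].iloc[0])
    assert runs[0] == runs[1]


def test_dataset_validation_errors():
    imgs = _images(2)
    with pytest.raises(ValueError, match="empty"):
        ReIDModel(np.empty((0, 64, 128, 3)), np.array([]), np.array([]))
    with pytest.raises(ValueError, match="never"):
        ReIDModel(imgs, np.array([0, 1]), np.array(["train", "val"]))
    with pytest.raises(ValueError, match="no training"):
        ReIDModel(imgs, np.array([0, 0]), np.array(["val", "val"]))


def test_save_and_restore_roundtrip(tmp_path, tiny_dataset):
    model = ReIDModel.from_dataset(tiny_dataset, config=TrainConfig(seed=1),
                                   profile="desk")
    res = model.fit(epochs=1)
    path = tmp_path / "w.npz"
    res.save(path)
    net2 = SerialReIDNet(num_classes=model.net.num_classes, profile="desk", seed=99)
    net2.load_state_dict(dict(np.load(path)))
    net2.eval()
    x = normalize_images(tiny_dataset.images[:2])
    np.testing.assert_allclose(net2.extract(x), model.net.extract(x), atol=1e-6)
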