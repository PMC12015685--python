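"""Adversarial model: activations, losses, batch balance, loop contracts."""

import numpy as np
import pytest
from scipy.special import expit, logsumexp

from phenogan import nn
from phenogan.chipio import ChipDataset, ImageChip
from phenogan.esgan import (DiscriminatorSpec, EsganModel, GeneratorSpec,
                            TrainConfig, generate_samples, generator_update,
                            predict_heading, prepare_inputs,
                            sample_balanced_batch, supervised_loss, train,
                            train_step, unsupervised_activation,
                            unsupervised_loss)

from conftest import make_plain_dataset


def tiny_model(seed=0):
    return EsganModel(GeneratorSpec(latent_dim=16, image_size=16,
                                    reshape_channels=16, mid_channels=8),
                      DiscriminatorSpec(image_size=16,
                                        channel_widths=(8, 8, 16, 16)),
                      seed=seed)


def batch(n, size=16, seed=0):
    rng = np.random.default_rng(seed)
    return rng.uniform(-1, 1, (n, size, size, 3)).astype(np.float32)


# ---------------------------------------------------------------------------
# activation and losses


def test_unsupervised_activation_hand_values():
    assert unsupervised_activation(np.array([0.0, 0.0])) == pytest.approx(2 / 3)
    with np.errstate(over="raise", invalid="raise"):
        low = unsupervised_activation(np.array([-1000.0, -1000.0]))
        high = unsupervised_activation(np.array([1000.0, 1000.0]))
    assert low < 1e-6 and high > 1 - 1e-12


def test_unsupervised_activation_equals_naive_ratio():
    """sigmoid(logsumexp(l)) == Z/(Z+1) at moderate magnitudes."""
    rng = np.random.default_rng(0)
    logits = rng.uniform(-20, 20, (1000, 2))
    ours = unsupervised_activation(logits)
    z = np.exp(logits).sum(axis=1)
    assert np.abs(ours - z / (z + 1)).max() < 1e-12
    assert np.allclose(ours, expit(logsumexp(logits, axis=1)), atol=1e-15)


def test_supervised_loss_hand_values():
    assert supervised_loss(np.array([[0.0, 1.0]]), [1]) == pytest.approx(0.0, abs=1e-6)
    assert supervised_loss(np.array([[0.5, 0.5]]), [0]) == pytest.approx(np.log(2))
    both = supervised_loss(np.array([[0.0, 1.0], [0.5, 0.5]]), [1, 0])
    assert both == pytest.approx(np.log(2) / 2, abs=1e-6)


def test_unsupervised_loss_hand_values():
    assert unsupervised_loss([1.0], [0.0]) == pytest.approx(0.0, abs=1e-6)
    assert unsupervised_loss([0.5], [0.5]) == pytest.approx(2 * np.log(2))
    assert unsupervised_loss([0.5], [0.5]) == unsupervised_loss([0.5], [0.5])


def test_losses_are_clamped_not_infinite():
    assert np.isfinite(supervised_loss(np.array([[1.0, 0.0]]), [1]))
    assert np.isfinite(unsupervised_loss([0.0], [1.0]))


# ---------------------------------------------------------------------------
# batch balance


def _tiny_chipset(n, label=0, size=16, seed=0):
    rng = np.random.default_rng(seed)
    chips = [ImageChip(rng.random((size, size, 3)).astype(np.float32))
             for _ in range(n)]
    return ChipDataset(chips, np.full(n, label), [f"x{seed}_{i}" for i in range(n)])


def test_balanced_batch_is_half_and_half():
    lab, unl = _tiny_chipset(100, 1, seed=1), _tiny_chipset(100, 0, seed=2)
    lh, uh = sample_balanced_batch(lab, unl, 64, np.random.default_rng(0))
    assert len(lh) == 32 and len(uh) == 32


def test_balanced_batch_pool_equal_to_half_uses_each_chip_once():
    lab = _tiny_chipset(32, 1, seed=3)
    unl = _tiny_chipset(100, 0, seed=4)
    lh, _ = sample_balanced_batch(lab, unl, 64, np.random.default_rng(0))
    assert sorted(lh.ids) == sorted(lab.ids)


def test_balanced_batch_small_pool_draws_with_replacement():
    lab = _tiny_chipset(10, 1, seed=5)
    unl = _tiny_chipset(100, 0, seed=6)
    lh, _ = sample_balanced_batch(lab, unl, 64, np.random.default_rng(0))
    assert len(lh) == 32
    base_ids = {i.split("@")[0] for i in lh.ids}     # multiset membership
    assert base_ids <= set(lab.ids)


def test_balanced_batch_rejects_empty_pool_and_odd_batch():
    lab = _tiny_chipset(4, 1)
    with pytest.raises(ValueError, match="empty"):
        sample_balanced_batch(lab, _tiny_chipset(2, 0).subset([]), 8,
                              np.random.default_rng(0))
    with pytest.raises(ValueError, match="even"):
        sample_balanced_batch(lab, lab, 7, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# training-loop contracts


def test_shared_backbone_supervised_update_moves_unsupervised_head():
    """One supervised-only update changes the real/fake probability too —
    the two heads literally share parameters."""
    model = tiny_model()
    probe = batch(4, seed=9)
    before = unsupervised_activation(model.disc_logits(probe))
    train_step(model, batch(8, seed=1), np.array([0, 1] * 4), None,
               np.random.default_rng(0))
    after = unsupervised_activation(model.disc_logits(probe))
    assert not np.allclose(before, after)


def test_supervised_only_step_leaves_generator_untouched():
    model = tiny_model()
    g_before = nn.param_hash(model.generator)
    train_step(model, batch(8, seed=1), np.array([0, 1] * 4), None,
               np.random.default_rng(0))
    assert nn.param_hash(model.generator) == g_before


def test_generator_update_freezes_discriminator():
    model = tiny_model()
    d_before = nn.param_hash(model.discriminator)
    z = np.random.default_rng(0).normal(size=(8, 16))
    loss = generator_update(model, z, batch(8, seed=2))
    assert loss >= 0.0
    assert nn.param_hash(model.discriminator) == d_before
    assert nn.param_hash(model.generator) != nn.param_hash(model.discriminator)


def test_generator_update_zero_loss_on_identical_batches():
    """Feature matching is exactly zero when 'real' chips are the fakes."""
    model = tiny_model()
    z = np.random.default_rng(1).normal(size=(6, 16))
    fakes = model.generate(z)
    loss = generator_update(model, z, fakes)
    assert loss == pytest.approx(0.0, abs=1e-8)


def test_full_train_step_updates_both_submodels_and_counts():
    model = tiny_model()
    g0, d0 = nn.param_hash(model.generator), nn.param_hash(model.discriminator)
    losses = train_step(model, batch(8, seed=1), np.array([0, 1] * 4),
                        batch(8, seed=2), np.random.default_rng(0))
    assert model.step_count == 1
    assert nn.param_hash(model.generator) != g0
    assert nn.param_hash(model.discriminator) != d0
    assert all(np.isfinite(v) for v in losses.values())
    assert all(v >= 0 for v in losses.values())


def test_train_step_is_bitwise_reproducible_from_checkpoint():
    model = tiny_model(seed=4)
    gs, ds = nn.get_state(model.generator), nn.get_state(model.discriminator)
    og, od = model.opt_g.state(), model.opt_d.state()
    lx, ly, ux = batch(8, seed=1), np.array([0, 1] * 4), batch(8, seed=2)
    l1 = train_step(model, lx, ly, ux, np.random.default_rng(99))
    h1 = (nn.param_hash(model.generator), nn.param_hash(model.discriminator))
    nn.set_state(model.generator, gs)
    nn.set_state(model.discriminator, ds)
    model.opt_g.load_state(og)
    model.opt_d.load_state(od)
    l2 = train_step(model, lx, ly, ux, np.random.default_rng(99))
    assert l1 == l2
    assert h1 == (nn.param_hash(model.generator),
                  nn.param_hash(model.discriminator))


def test_train_step_rejects_masked_labels():
    model = tiny_model()
    with pytest.raises(ValueError, match="masked"):
        train_step(model, batch(4), np.array([0, 1, -1, 1]), None,
                   np.random.default_rng(0))


# ---------------------------------------------------------------------------
# prediction and sampling


def test_predictions_sum_to_one_and_ignore_batch_order():
    model = tiny_model()
    x = batch(10, seed=3)
    probs = predict_heading(model, x)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    perm = np.random.default_rng(0).permutation(10)
    assert np.allclose(predict_heading(model, x[perm]), probs[perm])


def test_duplicated_chip_gets_identical_outputs():
    model = tiny_model()
    x = batch(1, seed=5)
    dup = np.concatenate([x, x])
    probs = predict_heading(model, dup)
    assert np.array_equal(probs[0], probs[1])


def test_predict_rejects_wrong_size_or_range():
    model = tiny_model()
    with pytest.raises(ValueError, match="expected"):
        predict_heading(model, np.zeros((2, 24, 24, 3), dtype=np.float32))
    with pytest.raises(ValueError, match="normalised"):
        predict_heading(model, np.full((2, 16, 16, 3), 3.0, dtype=np.float32))


def test_generated_samples_respect_tanh_range_and_determinism():
    model = tiny_model()
    a = generate_samples(model, 5, np.random.default_rng(8))
    b = generate_samples(model, 5, np.random.default_rng(8))
    for ca, cb in zip(a, b):
        assert ca.pixels.min() >= -1.0 and ca.pixels.max() <= 1.0
        assert np.array_equal(ca.pixels, cb.pixels)


def test_training_moves_the_generator():
    model = tiny_model()
    z = np.random.default_rng(0).normal(size=(4, 16))
    before = model.generate(z).copy()
    for _ in range(3):
        train_step(model, batch(8, seed=1), np.array([0, 1] * 4),
                   batch(8, seed=2), np.random.default_rng(1))
    after = model.generate(z)
    assert np.abs(after - before).mean() > 0.0


# ---------------------------------------------------------------------------
# epoch loop


def _val_set(n=6, size=16):
    rng = np.random.default_rng(0)
    chips = [ImageChip(rng.random((size, size, 3)).astype(np.float32))
             for _ in range(n)]
    return ChipDataset(chips, np.array([0, 1] * (n // 2)),
                       [f"v{i}" for i in range(n)])


def test_train_stops_after_two_epochs_when_metric_stalls(monkeypatch):
    import phenogan.esgan as es

    fixed = np.tile([[0.6, 0.4]], (6, 1))
    monkeypatch.setattr(es, "predict_heading", lambda m, x: fixed[:len(x)])
    model = tiny_model()
    labeled = _val_set()
    cfg = TrainConfig(batch_size=4, max_epochs=50, patience=1,
                      steps_per_epoch=1, seed=0)
    _, history = es.train(model, labeled, labeled.with_labels_masked(),
                          _val_set(), cfg)
    assert len(history) == 2


def test_train_history_is_bounded_and_validated():
    model = tiny_model()
    labeled = _val_set()
    cfg = TrainConfig(batch_size=4, max_epochs=3, patience=5,
                      steps_per_epoch=1, seed=0)
    _, history = train(model, labeled, labeled.with_labels_masked(),
                       _val_set(), cfg)
    assert len(history) <= 3
    assert set(history.columns) == {"epoch", "loss_sup", "loss_unsup_real",
                                    "loss_unsup_fake", "loss_gen", "val_oa"}
    with pytest.raises(ValueError, match="empty"):
        train(model, labeled, labeled, _val_set().subset([]), cfg)


def test_checkpoint_roundtrip(tmp_path):
    model = tiny_model(seed=7)
    train_step(model, batch(8, seed=1), np.array([0, 1] * 4), batch(8, seed=2),
               np.random.default_rng(0))
    path = tmp_path / "ckpt.npz"
    model.save(path)
    back = EsganModel.load(path)
    assert nn.param_hash(back.generator) == nn.param_hash(model.generator)
    assert nn.param_hash(back.discriminator) == nn.param_hash(model.discriminator)
    assert back.step_count == 1
    x = batch(3, seed=4)
    assert np.array_equal(predict_heading(back, x), predict_heading(model, x))
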