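import math

import numpy as np
import pytest

from vetgan import sgan
from conftest import tiny_sgan_config


def make_output(logits):
    logits = np.asarray(logits, dtype=np.float64)
    return sgan.DiscriminatorOutput(class_logits=logits,
                                    features=np.zeros((len(logits), 4)))


class TestConfig:
    def test_invalid_side_rejected(self):
        with pytest.raises(ValueError, match="multiple of 16"):
            sgan.SGANConfig(image_side=100)

    def test_patience_must_be_below_max_epochs(self):
        with pytest.raises(ValueError):
            sgan.SGANConfig(max_epochs=5, patience=5)

    def test_k_and_latent_bounds(self):
        with pytest.raises(ValueError):
            sgan.SGANConfig(k=1)
        with pytest.raises(ValueError):
            sgan.SGANConfig(latent_dim=0)


class TestGenerator:
    def test_output_shape_and_range(self):
        cfg = tiny_sgan_config(latent_dim=100)
        gen = sgan.build_generator(cfg, seed=0)
        z = np.random.default_rng(1).standard_normal((4, 100)).astype(np.float32)
        out = gen.forward(z, train=False)
        assert out.shape == (4, 32, 32, 3)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_eval_mode_deterministic(self):
        cfg = tiny_sgan_config()
        gen = sgan.build_generator(cfg, seed=3)
        z = np.random.default_rng(2).standard_normal((2, cfg.latent_dim)).astype(np.float32)
        assert (gen.forward(z, train=False) == gen.forward(z, train=False)).all()


class TestDiscriminator:
    def test_output_shapes(self):
        cfg = tiny_sgan_config(interpretation_width=16)
        disc = sgan.build_discriminator(cfg, seed=0)
        x = np.zeros((4, 32, 32, 3), dtype=np.float32)
        out = disc.forward(x, train=False)
        assert out.class_logits.shape == (4, cfg.k + 1)
        assert out.features.shape == (4, 16)

    def test_softmax_rows_normalized(self):
        cfg = tiny_sgan_config()
        disc = sgan.build_discriminator(cfg, seed=0)
        x = np.random.default_rng(0).standard_normal((4, 32, 32, 3)).astype(np.float32)
        out = disc.forward(x, train=True)
        p = sgan._softmax(out.class_logits)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_fresh_builds_differ(self):
        cfg = tiny_sgan_config()
        x = np.random.default_rng(0).standard_normal((2, 32, 32, 3)).astype(np.float32)
        a = sgan.build_discriminator(cfg, seed=1).forward(x, train=False)
        b = sgan.build_discriminator(cfg, seed=2).forward(x, train=False)
        assert not np.allclose(a.class_logits, b.class_logits)

    def test_pretrained_flag_unavailable(self):
        with pytest.raises(NotImplementedError):
            sgan.build_discriminator(tiny_sgan_config(pretrained=True), seed=0)


class TestSupervisedLoss:
    def test_zero_at_perfect_prediction(self):
        out = make_output([[30.0, 0.0, 0.0], [0.0, 30.0, 0.0]])
        loss = sgan.supervised_loss(out, np.array([0, 1]), k=2)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_uniform_logits_give_ln2(self):
        out = make_output([[0.0, 0.0, 5.0]])  # fake logit must not matter
        loss = sgan.supervised_loss(out, np.array([0]), k=2)
        assert loss == pytest.approx(math.log(2), abs=1e-9)

    def test_hand_worked_batch_of_three(self):
        logits = np.array([[1.0, -1.0, 0.3], [0.2, 0.9, -2.0], [0.0, 0.0, 1.0]])
        labels = np.array([0, 0, 1])
        expected = -np.mean([
            math.log(math.exp(1.0) / (math.exp(1.0) + math.exp(-1.0))),
            math.log(math.exp(0.2) / (math.exp(0.2) + math.exp(0.9))),
            math.log(0.5),
        ])
        loss = sgan.supervised_loss(make_output(logits), labels, k=2)
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_label(self):
        with pytest.raises(ValueError):
            sgan.supervised_loss(make_output([[0.0, 0.0, 0.0]]), np.array([2]), k=2)


class TestUnsupervisedLoss:
    def test_perfect_discrimination_near_zero(self):
        real = make_output([[20.0, 0.0, -20.0]])   # p(fake|real) ~ 0
        fake = make_output([[0.0, 0.0, 40.0]])     # p(fake|fake) ~ 1
        loss = sgan.unsupervised_loss(real, fake, k=2)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_half_fake_probability_gives_2ln2(self):
        # logits (0, 0, ln 2): softmax = (1/4, 1/4, 1/2)
        logits = [[0.0, 0.0, math.log(2)]]
        loss = sgan.unsupervised_loss(make_output(logits), make_output(logits), k=2)
        assert loss == pytest.approx(2 * math.log(2), abs=1e-9)

    def test_literal_flag_changes_only_fake_term(self):
        real = make_output([[1.0, 0.5, -0.2]])
        fake = make_output([[0.1, 0.2, 0.3]])
        standard = sgan.unsupervised_loss(real, fake, k=2, log_free_fake_term=False)
        literal = sgan.unsupervised_loss(real, fake, k=2, log_free_fake_term=True)
        real_term, _ = sgan._unsup_real_grad(real.class_logits, 2)
        p_fake = sgan._softmax(fake.class_logits)[:, 2].mean()
        assert literal == pytest.approx(real_term - p_fake, abs=1e-9)
        assert standard != literal

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            sgan.unsupervised_loss(make_output(np.empty((0, 3))),
                                   make_output([[0.0, 0.0, 0.0]]), k=2)


class TestFeatureMatchingLoss:
    def test_identical_batches_zero(self, rng):
        f = rng.normal(size=(5, 7))
        assert sgan.feature_matching_loss(f, f.copy()) == 0.0

    def test_constant_shift_gives_squared_norm(self, rng):
        f = rng.normal(size=(6, 4))
        c = np.array([1.0, -2.0, 0.5, 3.0])
        assert sgan.feature_matching_loss(f, f + c) == pytest.approx(
            float(c @ c), rel=1e-6
        )

    def test_brute_force_oracle(self, rng):
        a = rng.normal(size=(3, 4))
        b = rng.normal(size=(5, 4))
        diff = a.mean(axis=0) - b.mean(axis=0)
        assert sgan.feature_matching_loss(a, b) == pytest.approx(
            float((diff**2).sum()), rel=1e-9
        )

    def test_symmetry(self, rng):
        a, b = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        assert sgan.feature_matching_loss(a, b) == pytest.approx(
            sgan.feature_matching_loss(b, a)
        )

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            sgan.feature_matching_loss(rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))


class TestLossGradients:
    """Analytic loss gradients against finite differences of the scalar losses."""

    @pytest.mark.parametrize("fn,args", [
        (sgan._supervised_grad, (np.array([0, 1]), 2)),
        (sgan._unsup_real_grad, (2,)),
        (sgan._unsup_fake_grad, (2, False)),
        (sgan._unsup_fake_grad, (2, True)),
    ], ids=["supervised", "unsup_real", "unsup_fake_std", "unsup_fake_literal"])
    def test_gradient_matches(self, fn, args, rng):
        logits = rng.normal(size=(2, 3))
        _, grad = fn(logits, *args)
        eps = 1e-6
        for i in range(logits.shape[0]):
            for j in range(logits.shape[1]):
                lp = logits.copy(); lp[i, j] += eps
                lm = logits.copy(); lm[i, j] -= eps
                num = (fn(lp, *args)[0] - fn(lm, *args)[0]) / (2 * eps)
                assert grad[i, j] == pytest.approx(num, abs=1e-6)


class TestPixelScaling:
    def test_round_trip_recovers_uint8(self):
        imgs = np.arange(256, dtype=np.uint8).reshape(1, 16, 16, 1)
        imgs = np.repeat(imgs, 3, axis=3)
        assert (sgan.from_network(sgan.to_network(imgs)) == imgs).all()

    def test_range_is_tanh_compatible(self):
        x = sgan.to_network(np.array([[[[0, 128, 255]]]], dtype=np.uint8))
        assert x.min() == -1.0 and x.max() == 1.0


class TestEarlyStopping:
    def test_stops_at_patience_plus_one_without_improvement(self):
        stopper = sgan.EarlyStopping(patience=10)
        stopped_at = None
        for epoch in range(1, 100):
            if stopper.update(1.0):  # constant: no improvement after epoch 1
                stopped_at = epoch
                break
        assert stopped_at == 11
        assert stopper.best_epoch == 1

    def test_improvement_resets_counter(self):
        stopper = sgan.EarlyStopping(patience=2, min_delta=1e-4)
        assert not stopper.update(1.0)
        assert not stopper.update(0.9)
        assert not stopper.update(0.95)
        assert not stopper.update(0.8)
        assert not stopper.update(0.85)
        assert stopper.update(0.85)  # two straight non-improvements
        assert stopper.best_epoch == 4

    def test_sub_min_delta_change_is_no_improvement(self):
        stopper = sgan.EarlyStopping(patience=1, min_delta=1e-4)
        stopper.update(1.0)
        assert stopper.update(1.0 - 1e-5)


def split_sets(ds):
    labeled = sgan.ImageSet(ds.images[ds.labeled_indices], ds.labels[ds.labeled_indices])
    unlabeled = sgan.ImageSet(ds.images[ds.unlabeled_indices])
    return labeled, unlabeled


class TestTrain:
    def test_missing_class_rejected(self, tiny_dataset, tiny_config):
        labeled, unlabeled = split_sets(tiny_dataset)
        only_healthy = sgan.ImageSet(
            labeled.images[labeled.labels == 0], labeled.labels[labeled.labels == 0]
        )
        with pytest.raises(ValueError, match="every class"):
            sgan.train(only_healthy, unlabeled, labeled, tiny_config, seed=0)

    def test_history_and_additivity(self, tiny_dataset, tiny_config):
        labeled, unlabeled = split_sets(tiny_dataset)
        model = sgan.train(labeled, unlabeled, labeled, tiny_config, seed=0)
        st = model.state
        assert st.stopped_epoch == len(st.epochs) <= tiny_config.max_epochs
        for ld, ls, lu in zip(st.loss_discriminator, st.loss_supervised,
                              st.loss_unsupervised):
            assert ld == pytest.approx(ls + lu, abs=1e-6)
        assert all(lg >= 0 for lg in st.loss_generator)

    def test_seeded_training_reproducible(self, tiny_dataset, tiny_config):
        labeled, unlabeled = split_sets(tiny_dataset)
        m1 = sgan.train(labeled, unlabeled, labeled, tiny_config, seed=5)
        m2 = sgan.train(labeled, unlabeled, labeled, tiny_config, seed=5)
        assert m1.state.loss_discriminator == m2.state.loss_discriminator
        p1, f1 = sgan.predict(m1, tiny_dataset.images[:8])
        p2, f2 = sgan.predict(m2, tiny_dataset.images[:8])
        assert (p1 == p2).all() and (f1 == f2).all()


class TestPredict:
    def test_untrained_model_rejected(self, tiny_config):
        model = sgan.SGANModel(
            generator=sgan.build_generator(tiny_config),
            discriminator=sgan.build_discriminator(tiny_config),
            config=tiny_config, seed=0,
        )
        with pytest.raises(RuntimeError):
            sgan.predict(model, np.zeros((1, 32, 32, 3), dtype=np.uint8))

    def test_renormalization_arithmetic(self):
        # symmetric real logits with impossible fake class
        p = sgan._softmax(np.array([[0.0, 0.0, -1e9]]))
        real = p[0, :2] / p[0, :2].sum()
        assert real == pytest.approx([0.5, 0.5])
        assert p[0, 2] == pytest.approx(0.0)
        # logits (ln 3, 0, 0): renormalized real-class probabilities (0.75, 0.25)
        p = sgan._softmax(np.array([[math.log(3), 0.0, 0.0]]))
        real = p[0, :2] / p[0, :2].sum()
        assert real == pytest.approx([0.75, 0.25])

    def test_rows_sum_to_one(self, tiny_dataset, tiny_config):
        labeled, unlabeled = split_sets(tiny_dataset)
        model = sgan.train(labeled, unlabeled, labeled, tiny_config, seed=1)
        probs, fake = sgan.predict(model, tiny_dataset.images[:16])
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert ((fake >= 0) & (fake <= 1)).all()


class TestWidthSearch:
    def test_single_candidate_returned(self, tiny_dataset, tiny_config):
        labeled, unlabeled = split_sets(tiny_dataset)
        best, scores = sgan.search_interpretation_width(
            [8], labeled, unlabeled, labeled, tiny_config, seed=0, search_epochs=1
        )
        assert best == 8 and set(scores) == {8}

    def test_tie_broken_toward_smaller_width(self):
        assert sgan._select_best_width({64: 0.8, 128: 0.8}) == 64
        assert sgan._select_best_width({128: 0.9, 64: 0.8}) == 128

    def test_empty_candidates_rejected(self, tiny_dataset, tiny_config):
        labeled, unlabeled = split_sets(tiny_dataset)
        with pytest.raises(ValueError):
            sgan.search_interpretation_width(
                [], labeled, unlabeled, labeled, tiny_config
            )


def test_checkpoint_round_trip(tmp_path, tiny_dataset, tiny_config):
    labeled = sgan.ImageSet(
        tiny_dataset.images[tiny_dataset.labeled_indices],
        tiny_dataset.labels[tiny_dataset.labeled_indices],
    )
    unlabeled = sgan.ImageSet(tiny_dataset.images[tiny_dataset.unlabeled_indices])
    model = sgan.train(labeled, unlabeled, labeled, tiny_config, seed=2)
    sgan.save_checkpoint(model, tmp_path / "ckpt.npz")
    loaded = sgan.load_checkpoint(tmp_path / "ckpt.npz")
    assert loaded.config == model.config
    assert loaded.state.epochs == model.state.epochs
    p1, f1 = sgan.predict(model, tiny_dataset.images[:8])
    p2, f2 = sgan.predict(loaded, tiny_dataset.images[:8])
    assert np.allclose(p1, p2) and np.allclose(f1, f2)


def test_warmup_epochs_are_supervised_only(tiny_dataset):
    labeled, unlabeled = split_sets(tiny_dataset)
    cfg = tiny_sgan_config(max_epochs=2, patience=1, warmup_epochs=1)
    model = sgan.train(labeled, unlabeled, labeled, cfg, seed=3)
    st = model.state
    assert st.loss_unsupervised[0] == 0.0 and st.loss_generator[0] == 0.0
    if len(st.epochs) > 1:
        assert st.loss_unsupervised[1] > 0.0
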