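"""RDB-DCGAN: block algebra, architecture contracts at desk scale, loss
closed forms, gradient-penalty closed forms, and the training loop checked
against a hand-rolled oracle on a toy generator/discriminator pair."""

import numpy as np
import pytest

from somnogan import nn
from somnogan.containers import GENERATED, ImageSet
from somnogan.evaluation import PixelFeatures
from somnogan.rdb_dcgan import (
    RDB, RDN, DiscriminatorSpec, Discriminator, DivergedError, GANTrainConfig,
    Generator, GeneratorSpec, adversarial_losses, gradient_penalty,
    load_bundle, perceptual_loss, rdb_param_count, RDBSpec, sample_images,
    save_bundle, train_gan,
)
from somnogan.synthetic_data import synth_image_dataset

SMALL_GAN = dict(image_size=16, width_factor=1 / 8, n_rdb=1, rdb_layers=2,
                 rdb_growth=4, batch_size=8, log_every=10)


def _num_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestRDB:
    SPEC = RDBSpec(channels=4, n_conv_layers=2, growth=3)

    def test_preserves_shape(self):
        rdb = RDB(self.SPEC, np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 6, 6, 4))
        assert rdb.forward(x).shape == x.shape

    def test_channel_mismatch_rejected(self):
        rdb = RDB(self.SPEC, np.random.default_rng(0))
        with pytest.raises(ValueError):
            rdb.forward(np.zeros((1, 6, 6, 5)))

    def test_zero_parameters_give_residual_identity(self):
        rdb = RDB(self.SPEC, np.random.default_rng(0))
        for p in rdb.params():
            p.value[...] = 0.0
        x = np.random.default_rng(2).normal(size=(2, 5, 5, 4))
        assert np.array_equal(rdb.forward(x), x)

    @pytest.mark.parametrize("spec", [
        RDBSpec(4, 2, 3), RDBSpec(8, 3, 4), RDBSpec(256, 3, 32),
    ])
    def test_parameter_count_matches_closed_form(self, spec):
        rdb = RDB(spec, np.random.default_rng(0))
        assert rdb.n_params() == rdb_param_count(spec)

    def test_backward_matches_finite_differences(self):
        rdb = RDB(self.SPEC, np.random.default_rng(3))
        x = np.random.default_rng(4).normal(size=(1, 4, 4, 4))
        r = np.random.default_rng(5).normal(size=(1, 4, 4, 4))

        def loss():
            return float((rdb.forward(x) * r).sum())

        rdb.zero_grad()
        rdb.forward(x)
        dx = rdb.backward(r)
        assert np.allclose(dx, _num_grad(loss, x), atol=1e-6)
        for p in rdb.params():
            assert np.allclose(p.grad, _num_grad(loss, p.value), atol=1e-6)


def test_rdn_backward_matches_finite_differences():
    rdn = RDN(channels=3, n_blocks=2, rng=np.random.default_rng(0),
              rdb_layers=2, growth=2)
    x = np.random.default_rng(1).normal(size=(1, 4, 4, 3))
    r = np.random.default_rng(2).normal(size=(1, 4, 4, 3))

    def loss():
        return float((rdn.forward(x) * r).sum())

    rdn.zero_grad()
    rdn.forward(x)
    dx = rdn.backward(r)
    assert np.allclose(dx, _num_grad(loss, x), atol=1e-6)
    for p in rdn.params():
        assert np.allclose(p.grad, _num_grad(loss, p.value), atol=1e-6)


class TestArchitectures:
    GSPEC = GeneratorSpec(base_size=32, width_factor=1 / 8, n_rdb=2,
                          rdb_layers=2, rdb_growth=4)
    DSPEC = DiscriminatorSpec(base_size=32, width_factor=1 / 8)

    def test_generator_output_shape_and_range(self):
        g = Generator(self.GSPEC, np.random.default_rng(0))
        z = np.random.default_rng(1).standard_normal((5, 100))
        y = g.forward(z)
        assert y.shape == (5, 32, 32, 3)
        assert y.min() >= -1.0 and y.max() <= 1.0

    def test_generator_deterministic_in_inference(self):
        g = Generator(self.GSPEC, np.random.default_rng(0))
        z = np.random.default_rng(2).standard_normal((3, 100))
        assert np.array_equal(g.forward(z), g.forward(z))

    def test_generator_rejects_wrong_noise_length(self):
        g = Generator(self.GSPEC, np.random.default_rng(0))
        with pytest.raises(ValueError):
            g.forward(np.zeros((2, 99)))

    def test_generator_shape_chain(self):
        assert self.GSPEC.shape_chain() == [
            (2, 2, 64), (4, 4, 32), (8, 8, 16), (16, 16, 8), (32, 32, 3)]

    def test_discriminator_probabilities_and_preflatten(self):
        d = Discriminator(self.DSPEC, np.random.default_rng(0))
        imgs = np.random.default_rng(1).uniform(-1, 1, size=(7, 32, 32, 3))
        p = d.forward(imgs)
        assert p.shape == (7,)
        assert np.all((p >= 0) & (p <= 1))
        assert d.features(imgs).shape[1:] == (2, 2, 64)
        assert d.preflatten_shape == (2, 2, 64)

    def test_discriminator_rejects_wrong_shape(self):
        d = Discriminator(self.DSPEC, np.random.default_rng(0))
        with pytest.raises(ValueError):
            d.forward(np.zeros((2, 16, 16, 3)))

    def test_zero_parameter_discriminator_outputs_half(self):
        d = Discriminator(self.DSPEC, np.random.default_rng(0))
        for p in d.params():
            p.value[...] = 0.0
        imgs = np.random.default_rng(2).uniform(-1, 1, size=(4, 32, 32, 3))
        assert np.allclose(d.forward(imgs), 0.5)


class TestLosses:
    def test_perfect_discriminator_loss_near_zero(self):
        d_loss, _ = adversarial_losses(np.ones(8), np.zeros(8))
        assert d_loss < 1e-5

    def test_uninformative_discriminator_gives_2ln2(self):
        d_loss, g_adv = adversarial_losses(np.full(8, 0.5), np.full(8, 0.5))
        assert d_loss == pytest.approx(2 * np.log(2), abs=1e-12)
        assert g_adv == pytest.approx(np.log(2), abs=1e-12)

    def test_saturating_mode(self):
        _, g_adv = adversarial_losses(np.full(4, 0.5), np.full(4, 0.5),
                                      saturating=True)
        assert g_adv == pytest.approx(np.log(0.5), abs=1e-12)

    def test_empty_batches_rejected(self):
        with pytest.raises(ValueError):
            adversarial_losses(np.array([]), np.array([]))

    def test_perceptual_loss_zero_on_identical(self):
        imgs = np.random.default_rng(0).normal(size=(4, 2, 2, 1))
        assert perceptual_loss(imgs, imgs, PixelFeatures()) == 0.0

    def test_perceptual_loss_hand_value_on_identity_features(self):
        """2x2x1 images differing by +1 everywhere: ||Δ||² = 4, w·h·d = 4."""
        real = np.zeros((3, 2, 2, 1))
        gen = np.ones((3, 2, 2, 1))
        assert perceptual_loss(gen, real, PixelFeatures()) == \
            pytest.approx(1.0, abs=1e-12)

    def test_perceptual_loss_nonnegative(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.normal(size=(2, 3, 3, 1))
            b = rng.normal(size=(2, 3, 3, 1))
            assert perceptual_loss(a, b, PixelFeatures()) >= 0.0

    def test_perceptual_loss_shape_mismatch(self):
        with pytest.raises(ValueError):
            perceptual_loss(np.zeros((2, 2, 2, 1)), np.zeros((2, 3, 3, 1)),
                            PixelFeatures())


class _LinearDisc(nn.Sequential):
    """D(x) = <w, x>: input gradient is w everywhere."""

    def __init__(self, shape, w):
        dense = nn.Dense(int(np.prod(shape)), 1, np.random.default_rng(0),
                         bias=False)
        dense.W.value[:, 0] = w.ravel()
        super().__init__(nn.Flatten(), dense)


class TestGradientPenalty:
    def test_unit_gradient_gives_zero_penalty(self):
        shape = (2, 2, 3)
        w = np.zeros(12)
        w[0] = 1.0  # unit L2 norm
        d = _LinearDisc(shape, w)
        rng = np.random.default_rng(0)
        real = rng.normal(size=(6,) + shape)
        fake = rng.normal(size=(6,) + shape)
        assert gradient_penalty(d, real, fake, rng) == \
            pytest.approx(0.0, abs=1e-12)

    def test_constant_gradient_norm_three_gives_four(self):
        shape = (2, 2, 3)
        w = np.zeros(12)
        w[3] = 3.0  # ||w|| = 3 -> (3-1)^2 = 4
        d = _LinearDisc(shape, w)
        rng = np.random.default_rng(1)
        real = rng.normal(size=(5,) + shape)
        fake = rng.normal(size=(5,) + shape)
        assert gradient_penalty(d, real, fake, rng) == \
            pytest.approx(4.0, abs=1e-10)

    def test_penalty_nonnegative_for_real_discriminator(self):
        d = Discriminator(DiscriminatorSpec(base_size=16, width_factor=1 / 8),
                          np.random.default_rng(0))
        rng = np.random.default_rng(2)
        real = rng.uniform(-1, 1, size=(4, 16, 16, 3))
        fake = rng.uniform(-1, 1, size=(4, 16, 16, 3))
        assert gradient_penalty(d, real, fake, rng) >= 0.0


@pytest.fixture(scope="module")
def tiny_images():
    return synth_image_dataset({"N1": 64}, (16, 16), seed=0)


class TestTraining:
    def test_smoke_run_finite_and_eq4(self, tiny_images):
        cfg = GANTrainConfig(iterations=30, seed=1, **SMALL_GAN)
        bundle = train_gan(tiny_images, cfg, stage="N1")
        h = bundle.history
        assert len(h["iteration"]) >= 3
        for key in ("d_loss", "g_adv", "g_perceptual", "g_total", "gp"):
            assert np.all(np.isfinite(h[key]))
        # combined objective: g_total = g_adv + λ₁ · g_perceptual
        assert np.allclose(np.array(h["g_total"]),
                           np.array(h["g_adv"])
                           + cfg.lambda_perceptual * np.array(h["g_perceptual"]),
                           atol=1e-12)

    def test_zero_weights_reduce_total_to_adversarial(self, tiny_images):
        cfg = GANTrainConfig(iterations=12, seed=2, lambda_perceptual=0.0,
                             lambda_gp=0.0, **SMALL_GAN)
        bundle = train_gan(tiny_images, cfg)
        h = bundle.history
        assert h["g_total"] == h["g_adv"]
        assert all(v == 0.0 for v in h["gp"])

    def test_seed_reproducibility(self, tiny_images):
        cfg = GANTrainConfig(iterations=10, seed=7, **SMALL_GAN)
        b1 = train_gan(tiny_images, cfg, stage="N1")
        b2 = train_gan(tiny_images, cfg, stage="N1")
        for a, b in zip(nn.get_state(b1.generator), nn.get_state(b2.generator)):
            assert np.array_equal(a, b)
        for a, b in zip(nn.get_state(b1.discriminator),
                        nn.get_state(b2.discriminator)):
            assert np.array_equal(a, b)

    def test_empty_dataset_rejected(self):
        cfg = GANTrainConfig(iterations=1, **SMALL_GAN)
        with pytest.raises(ValueError):
            train_gan(ImageSet.empty((16, 16)), cfg)

    def test_nonfinite_input_raises_diverged(self, tiny_images):
        bad = ImageSet(np.full((16, 16, 16, 3), np.nan),
                       np.full(16, "N1", dtype=object))
        cfg = GANTrainConfig(iterations=3, seed=0, **SMALL_GAN)
        with pytest.raises(DivergedError):
            train_gan(bad, cfg)

    def test_sampling_contracts(self, tiny_images):
        cfg = GANTrainConfig(iterations=5, seed=3, **SMALL_GAN)
        bundle = train_gan(tiny_images, cfg, stage="N1")
        assert len(sample_images(bundle, 0)) == 0
        s1 = sample_images(bundle, 10, seed=5)
        s2 = sample_images(bundle, 10, seed=5)
        assert np.array_equal(s1.pixels, s2.pixels)
        assert s1.pixels.shape == (10, 16, 16, 3)
        assert s1.pixels.min() >= -1 and s1.pixels.max() <= 1
        assert all(p == GENERATED for p in s1.provenance)
        assert all(s == "N1" for s in s1.stages)
        with pytest.raises(ValueError):
            sample_images(bundle, -1)

    def test_checkpoint_roundtrip(self, tiny_images, tmp_path):
        cfg = GANTrainConfig(iterations=5, seed=4, **SMALL_GAN)
        bundle = train_gan(tiny_images, cfg, stage="N2")
        path = tmp_path / "bundle.npz"
        save_bundle(bundle, path)
        back = load_bundle(path)
        assert back.stage == "N2"
        assert np.array_equal(sample_images(back, 4, seed=1).pixels,
                              sample_images(bundle, 4, seed=1).pixels)


class TestTrainingOracle:
    """One D step + one G step on scalar-ish toys reproduces a hand-rolled
    Adam update (λ₁ = λ_gp = 0, minimax generator loss)."""

    def test_single_iteration_matches_hand_rolled_update(self):
        seed, bs, zdim = 13, 4, 1
        rng_data = np.random.default_rng(100)
        X = rng_data.normal(size=(10, 1, 1, 3))
        images = ImageSet(X, np.full(10, "N1", dtype=object))

        g_dense = nn.Dense(zdim, 3, np.random.default_rng(1), bias=False)
        generator = nn.Sequential(g_dense, nn.Reshape((1, 1, 3)))
        d_dense = nn.Dense(3, 1, np.random.default_rng(2), bias=False)
        discriminator = nn.Sequential(nn.Flatten(), d_dense, nn.Sigmoid())
        wg0 = g_dense.W.value.copy()          # (1, 3)
        wd0 = d_dense.W.value.copy()          # (3, 1)

        cfg = GANTrainConfig(iterations=1, batch_size=bs, seed=seed,
                             lambda_perceptual=0.0, lambda_gp=0.0,
                             saturating_g=True, z_dim=zdim, image_size=16,
                             log_every=1)
        train_gan(images, cfg, generator=generator,
                  discriminator=discriminator)

        # --- hand-rolled oracle, replaying the loop's RNG stream
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, 10, size=bs)
        real = X[idx].reshape(bs, 3)
        z = rng.standard_normal((bs, zdim))
        fake = z @ wg0                          # (bs, 3)
        eps = 1e-7

        def sigmoid(v):
            return 1 / (1 + np.exp(-v))

        def adam_step(w, g, lr, b1=0.5, b2=0.999, aeps=1e-8):
            m, v = (1 - b1) * g, (1 - b2) * g ** 2
            lr_t = lr * np.sqrt(1 - b2) / (1 - b1)
            return w - lr_t * m / (np.sqrt(v) + aeps)

        # D step: d_loss = -mean ln D(r) - mean ln(1 - D(f))
        dr = np.clip(sigmoid(real @ wd0)[:, 0], eps, 1 - eps)
        df = np.clip(sigmoid(fake @ wd0)[:, 0], eps, 1 - eps)
        dlogit_r = (-1 / (bs * dr)) * dr * (1 - dr)
        dlogit_f = (1 / (bs * (1 - df))) * df * (1 - df)
        gWd = real.T @ dlogit_r[:, None] + fake.T @ dlogit_f[:, None]
        wd1 = adam_step(wd0, gWd, cfg.lr_d)

        # G step (minimax): g_adv = mean ln(1 - D(G(z2)))
        z2 = rng.standard_normal((bs, zdim))
        fake2 = z2 @ wg0
        df2 = np.clip(sigmoid(fake2 @ wd1)[:, 0], eps, 1 - eps)
        dprob = -1 / (bs * (1 - df2))
        dlogit2 = dprob * df2 * (1 - df2)
        dfake2 = dlogit2[:, None] @ wd1.T       # (bs, 3)
        gWg = z2.T @ dfake2
        wg1 = adam_step(wg0, gWg, cfg.lr_g)

        assert np.allclose(d_dense.W.value, wd1, atol=1e-12)
        assert np.allclose(g_dense.W.value, wg1, atol=1e-12)
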