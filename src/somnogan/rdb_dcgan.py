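"""Residual-dense-block DCGAN for per-stage time–frequency image synthesis.

The generator projects a 100-d standard-normal noise vector to a
(6, 6, 512) tensor and upsamples through four stride-2 transposed
convolutions (kernel 3) to a (96, 96, 3) Tanh image, with a residual dense
network (RDN) of six residual dense blocks (RDBs) inserted after the first
and second upsampling stages.  An RDB chains densely connected 3×3
convolutions, fuses them with a 1×1 convolution and adds the block input
(local residual); the RDN concatenates all block outputs, fuses them with a
1×1 then 3×3 convolution and adds the RDN input (global input–output
fusion).  The discriminator mirrors DCGAN: four 5×5 stride-2 convolutions
(3→64→128→256→512 channels, LeakyReLU, batch norm except on the first
layer), flatten, and a single sigmoid unit.

Training combines a cross-entropy adversarial loss, a perceptual
(feature-matching) loss weighted by λ₁ = 0.1, and a two-sided gradient
penalty on interpolated samples, with Adam at the conventional per-network
learning rates (D 0.0002, G 0.0005).

A ``width_factor`` / smaller base size shrinks the identical architecture
for CPU-scale runs; the code path is the same at every scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .containers import GENERATED, ImageSet
from .evaluation import RandomConvFeatures

__all__ = [
    "RDBSpec", "RDB", "RDN", "GeneratorSpec", "DiscriminatorSpec",
    "Generator", "Discriminator", "GANTrainConfig", "LossComponents",
    "DivergedError", "adversarial_losses", "perceptual_loss",
    "gradient_penalty", "train_gan", "sample_images", "GANBundle",
    "save_bundle", "load_bundle", "rdb_param_count",
]


# ---------------------------------------------------------------------------
# residual dense blocks

@dataclass(frozen=True)
class RDBSpec:
    """Residual dense block: ``n_conv_layers`` densely connected 3×3 convs
    of ``growth`` channels each, a 1×1 local-fusion conv back to
    ``channels``, and a local residual connection (output channels equal
    input channels)."""

    channels: int
    n_conv_layers: int = 3
    growth: int = 32

    def __post_init__(self) -> None:
        if self.n_conv_layers < 1:
            raise ValueError("RDB needs at least one conv layer")
        if self.channels < 1 or self.growth < 1:
            raise ValueError("channels and growth must be positive")


def rdb_param_count(spec: RDBSpec) -> int:
    """Closed-form parameter count of one RDB (weights + biases)."""
    c, g, n = spec.channels, spec.growth, spec.n_conv_layers
    dense = sum(9 * (c + i * g) * g + g for i in range(n))
    fusion = (c + n * g) * c + c
    return dense + fusion


class RDB(nn.Layer):
    def __init__(self, spec: RDBSpec, rng: np.random.Generator,
                 w_std: float | None = 0.02) -> None:
        self.spec = spec
        c, g = spec.channels, spec.growth
        self.convs = [nn.Conv2D(c + i * g, g, 3, rng, w_std=w_std)
                      for i in range(spec.n_conv_layers)]
        self.relus = [nn.ReLU() for _ in self.convs]
        self.fusion = nn.Conv2D(c + spec.n_conv_layers * g, c, 1, rng,
                                w_std=w_std)

    def params(self):
        out = []
        for conv in self.convs:
            out.extend(conv.params())
        out.extend(self.fusion.params())
        return out

    def sublayers(self):
        return [*self.convs, *self.relus, self.fusion]

    def forward(self, x, train=False):
        if x.shape[-1] != self.spec.channels:
            raise ValueError(f"expected {self.spec.channels} channels, "
                             f"got {x.shape[-1]}")
        feats = x
        for conv, relu in zip(self.convs, self.relus):
            h = relu.forward(conv.forward(feats, train), train)
            feats = np.concatenate([feats, h], axis=-1)
        return self.fusion.forward(feats, train) + x

    def backward(self, dout):
        g = self.spec.growth
        dfeats = self.fusion.backward(dout)
        for conv, relu in zip(reversed(self.convs), reversed(self.relus)):
            dh = dfeats[..., -g:]
            dfeats = dfeats[..., :-g] + conv.backward(relu.backward(dh))
        return dfeats + dout


class RDN(nn.Layer):
    """Chain of RDBs with global feature fusion: concatenate every block's
    output, fuse with 1×1 then 3×3 convolutions, add the RDN input."""

    def __init__(self, channels: int, n_blocks: int, rng: np.random.Generator,
                 rdb_layers: int = 3, growth: int = 32,
                 w_std: float | None = 0.02) -> None:
        self.channels = channels
        spec = RDBSpec(channels, rdb_layers, growth)
        self.blocks = [RDB(spec, rng, w_std) for _ in range(n_blocks)]
        self.fuse1 = nn.Conv2D(channels * n_blocks, channels, 1, rng,
                               w_std=w_std)
        self.fuse3 = nn.Conv2D(channels, channels, 3, rng, w_std=w_std)

    def params(self):
        out = []
        for b in self.blocks:
            out.extend(b.params())
        out.extend(self.fuse1.params())
        out.extend(self.fuse3.params())
        return out

    def sublayers(self):
        return [*self.blocks, self.fuse1, self.fuse3]

    def forward(self, x, train=False):
        outs = []
        h = x
        for block in self.blocks:
            h = block.forward(h, train)
            outs.append(h)
        cat = np.concatenate(outs, axis=-1)
        return self.fuse3.forward(self.fuse1.forward(cat, train), train) + x

    def backward(self, dout):
        c = self.channels
        dcat = self.fuse1.backward(self.fuse3.backward(dout))
        dh = np.zeros_like(dout)
        for i in reversed(range(len(self.blocks))):
            dh = dh + dcat[..., i * c:(i + 1) * c]
            dh = self.blocks[i].backward(dh)
        return dh + dout


# ---------------------------------------------------------------------------
# generator / discriminator

@dataclass(frozen=True)
class GeneratorSpec:
    """Architecture knobs; defaults reproduce the full-scale network.

    ``base_size`` must be divisible by 16 (four stride-2 upsamplings);
    ``width_factor`` scales every channel width for desk-scale runs.
    """

    base_size: int = 96
    z_dim: int = 100
    width_factor: float = 1.0
    n_rdb: int = 6
    rdb_layers: int = 3
    rdb_growth: int = 32
    bn_momentum: float = 0.9
    w_std: float = 0.02

    def channels(self) -> tuple[int, int, int, int]:
        w = self.width_factor
        return tuple(max(4, int(round(c * w))) for c in (512, 256, 128, 64))

    def shape_chain(self) -> list[tuple[int, int, int]]:
        if self.base_size % 16:
            raise ValueError("base_size must be divisible by 16")
        s0 = self.base_size // 16
        c = self.channels()
        return [(s0, s0, c[0]), (2 * s0, 2 * s0, c[1]),
                (4 * s0, 4 * s0, c[2]), (8 * s0, 8 * s0, c[3]),
                (16 * s0, 16 * s0, 3)]


class Generator(nn.Layer):
    """Noise (n, z_dim) → images (n, base_size, base_size, 3) in [−1, 1]."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator) -> None:
        self.spec = spec
        chain = spec.shape_chain()
        s0 = spec.base_size // 16
        c0, c1, c2, c3 = spec.channels()
        growth = max(2, int(round(spec.rdb_growth * spec.width_factor)))
        m, ws = spec.bn_momentum, spec.w_std

        def tconv(ci, co):
            return nn.ConvTranspose2D(ci, co, rng, kernel=3, stride=2,
                                      padding=1, output_padding=1, w_std=ws)

        self.net = nn.Sequential(
            nn.Dense(spec.z_dim, s0 * s0 * c0, rng, w_std=ws),
            nn.Reshape((s0, s0, c0)),
            nn.BatchNorm(c0, momentum=m), nn.ReLU(),
            tconv(c0, c1), nn.BatchNorm(c1, momentum=m), nn.ReLU(),
            RDN(c1, spec.n_rdb, rng, spec.rdb_layers, growth, ws),
            tconv(c1, c2), nn.BatchNorm(c2, momentum=m), nn.ReLU(),
            RDN(c2, spec.n_rdb, rng, spec.rdb_layers, growth, ws),
            tconv(c2, c3), nn.BatchNorm(c3, momentum=m), nn.ReLU(),
            tconv(c3, 3), nn.Tanh(),
        )
        # assert the shape chain by construction on a dummy batch
        probe = np.zeros((1, spec.z_dim))
        x = probe
        expect = iter(chain)
        stage_ends = {1: 0, 6: 1, 10: 2, 13: 3, 15: 4}  # layer idx -> chain idx
        for li, layer in enumerate(self.net.layers):
            x = layer.forward(x, train=False)
            if li in stage_ends:
                want = chain[stage_ends[li]]
                if x.shape[1:] != want:
                    raise AssertionError(
                        f"shape chain broken at layer {li}: {x.shape[1:]} "
                        f"!= {want}")

    def params(self):
        return self.net.params()

    def sublayers(self):
        return [self.net]

    def forward(self, z, train=False):
        z = np.asarray(z, dtype=float)
        if z.ndim != 2 or z.shape[1] != self.spec.z_dim:
            raise ValueError(f"noise must be (n, {self.spec.z_dim})")
        return self.net.forward(z, train=train)

    def backward(self, dout):
        return self.net.backward(dout)


@dataclass(frozen=True)
class DiscriminatorSpec:
    base_size: int = 96
    width_factor: float = 1.0
    leaky_alpha: float = 0.2
    bn_momentum: float = 0.9
    w_std: float = 0.02

    def channels(self) -> tuple[int, int, int, int]:
        w = self.width_factor
        return tuple(max(4, int(round(c * w))) for c in (64, 128, 256, 512))


class Discriminator(nn.Layer):
    """Images (n, s, s, 3) → real-image probability in [0, 1] per image."""

    def __init__(self, spec: DiscriminatorSpec,
                 rng: np.random.Generator) -> None:
        self.spec = spec
        if spec.base_size % 16:
            raise ValueError("base_size must be divisible by 16")
        c1, c2, c3, c4 = spec.channels()
        a, m, ws = spec.leaky_alpha, spec.bn_momentum, spec.w_std
        sf = spec.base_size // 16
        self.feature_net = nn.Sequential(
            nn.Conv2D(3, c1, 5, rng, stride=2, w_std=ws), nn.LeakyReLU(a),
            nn.Conv2D(c1, c2, 5, rng, stride=2, w_std=ws),
            nn.BatchNorm(c2, momentum=m), nn.LeakyReLU(a),
            nn.Conv2D(c2, c3, 5, rng, stride=2, w_std=ws),
            nn.BatchNorm(c3, momentum=m), nn.LeakyReLU(a),
            nn.Conv2D(c3, c4, 5, rng, stride=2, w_std=ws),
            nn.BatchNorm(c4, momentum=m), nn.LeakyReLU(a),
        )
        self.head = nn.Sequential(nn.Flatten(),
                                  nn.Dense(sf * sf * c4, 1, rng, w_std=ws),
                                  nn.Sigmoid())
        self.preflatten_shape = (sf, sf, c4)

    def params(self):
        return self.feature_net.params() + self.head.params()

    def sublayers(self):
        return [self.feature_net, self.head]

    def _check(self, images):
        s = self.spec.base_size
        if images.ndim != 4 or images.shape[1:] != (s, s, 3):
            raise ValueError(f"expected images (n, {s}, {s}, 3), "
                             f"got {images.shape}")

    def features(self, images, train=False):
        self._check(images)
        return self.feature_net.forward(images, train=train)

    def forward(self, images, train=False):
        feats = self.features(np.asarray(images, dtype=float), train)
        return self.head.forward(feats, train=train)[:, 0]

    def backward(self, dout):
        dfeats = self.head.backward(np.asarray(dout)[:, None])
        return self.feature_net.backward(dfeats)


# ---------------------------------------------------------------------------
# losses

_EPS = 1e-7


@dataclass
class LossComponents:
    """All loss terms of one training step; ``g_total = g_adv + λ₁·g_perc``."""

    d_loss: float
    g_adv: float
    g_perceptual: float
    g_total: float
    gp: float
    d_real_mean: float
    d_fake_mean: float

    def finite(self) -> bool:
        return all(np.isfinite(v) for v in
                   (self.d_loss, self.g_adv, self.g_perceptual, self.g_total,
                    self.gp))


def adversarial_losses(d_real: np.ndarray, d_fake: np.ndarray,
                       saturating: bool = False,
                       eps: float = _EPS) -> tuple[float, float]:
    """Cross-entropy adversarial losses from discriminator probabilities.

    D minimises ``-E[ln D(x)] - E[ln(1 - D(G(z)))]``.  The generator term is
    the non-saturating ``-E[ln D(G(z))]`` by default; ``saturating=True``
    gives the minimax form ``E[ln(1 - D(G(z)))]``.
    """
    d_real = np.clip(np.asarray(d_real, float), eps, 1 - eps)
    d_fake = np.clip(np.asarray(d_fake, float), eps, 1 - eps)
    if d_real.size == 0 or d_fake.size == 0:
        raise ValueError("empty probability batches")
    d_loss = float(-np.mean(np.log(d_real)) - np.mean(np.log(1 - d_fake)))
    if saturating:
        g_adv = float(np.mean(np.log(1 - d_fake)))
    else:
        g_adv = float(-np.mean(np.log(d_fake)))
    return d_loss, g_adv


def _feature_map(extractor, pixels, for_backward=False):
    if hasattr(extractor, "net"):
        return extractor.net.forward(np.asarray(pixels, float), train=False)
    return extractor(np.asarray(pixels, float))


def perceptual_loss(gen_images: np.ndarray, real_images: np.ndarray,
                    extractor) -> float:
    """Feature-space distance ``mean_n ||F(g) - F(x)||_F^2 / (w·h·d)``.

    ``extractor`` is a frozen feature map; the normaliser is the product of
    all non-batch feature dimensions.
    """
    gen_images = np.asarray(gen_images, float)
    real_images = np.asarray(real_images, float)
    if gen_images.shape != real_images.shape:
        raise ValueError("generated and real batches must have equal shapes")
    fr = _feature_map(extractor, real_images)
    fg = _feature_map(extractor, gen_images)
    whd = int(np.prod(fg.shape[1:]))
    diff = fg - fr
    return float(np.mean(np.sum(diff.reshape(len(diff), -1) ** 2,
                                axis=1)) / whd)


def _perceptual_loss_and_grad(gen_images, real_images, extractor,
                              real_features=None):
    """Loss plus its gradient w.r.t. the generated pixels (extractor must
    expose a backpropable ``.net``)."""
    fr = real_features if real_features is not None \
        else _feature_map(extractor, real_images)
    fg = _feature_map(extractor, gen_images)  # cached last: backward valid
    whd = int(np.prod(fg.shape[1:]))
    diff = fg - fr
    loss = float(np.mean(np.sum(diff.reshape(len(diff), -1) ** 2,
                                axis=1)) / whd)
    dfg = 2.0 * diff / (whd * len(diff))
    if hasattr(extractor, "net"):
        extractor.net.zero_grad()
        dpix = extractor.net.backward(dfg)
        extractor.net.zero_grad()
    else:  # identity-style extractor
        dpix = dfg.reshape(gen_images.shape)
    return loss, dpix


def gradient_penalty(discriminator, real_batch: np.ndarray,
                     fake_batch: np.ndarray,
                     rng: np.random.Generator) -> float:
    """Two-sided penalty ``mean (||∇_x D(x̂)|| − 1)²`` on random interpolates
    ``x̂ = u·x_real + (1−u)·x_fake``.  Parameter gradients accumulated while
    computing the input gradient are discarded.
    """
    value, _, _, _ = _gradient_penalty_parts(discriminator, real_batch,
                                             fake_batch, rng)
    return value


def _gradient_penalty_parts(discriminator, real_batch, fake_batch, rng):
    real_batch = np.asarray(real_batch, float)
    fake_batch = np.asarray(fake_batch, float)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have equal shapes")
    n = len(real_batch)
    u = rng.uniform(size=(n,) + (1,) * (real_batch.ndim - 1))
    xhat = u * real_batch + (1 - u) * fake_batch
    discriminator.zero_grad()
    out = discriminator.forward(xhat, train=False)
    dx = discriminator.backward(np.ones_like(np.asarray(out)))
    discriminator.zero_grad()
    norms = np.sqrt(np.sum(dx.reshape(n, -1) ** 2, axis=1))
    value = float(np.mean((norms - 1.0) ** 2))
    return value, xhat, dx, norms


# ---------------------------------------------------------------------------
# training

@dataclass
class GANTrainConfig:
    """Hyperparameters; defaults are the full-scale training settings
    (Adam with D lr 2e-4 / G lr 5e-4, LeakyReLU α 0.2, batch-norm momentum
    0.9, 25 000 iterations, batch 64, λ₁ = 0.1, gradient-penalty weight 10).
    """

    lr_d: float = 0.0002
    lr_g: float = 0.0005
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    leaky_alpha: float = 0.2
    bn_momentum: float = 0.9
    iterations: int = 25000
    batch_size: int = 64
    lambda_perceptual: float = 0.1
    lambda_gp: float = 10.0
    seed: int = 0
    saturating_g: bool = False
    image_size: int = 96
    width_factor: float = 1.0
    n_rdb: int = 6
    rdb_layers: int = 3
    rdb_growth: int = 32
    z_dim: int = 100
    log_every: int = 100
    gp_fd_eps: float = 1e-3
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if min(self.lr_d, self.lr_g) <= 0:
            raise ValueError("learning rates must be positive")
        if self.lambda_perceptual < 0 or self.lambda_gp < 0:
            raise ValueError("loss weights must be non-negative")


class DivergedError(RuntimeError):
    def __init__(self, iteration: int, message: str = "") -> None:
        super().__init__(f"training diverged at iteration {iteration}"
                         + (f": {message}" if message else ""))
        self.iteration = iteration


@dataclass
class GANBundle:
    """One trained per-stage GAN: networks, specs, config and history."""

    generator: Generator | nn.Layer
    discriminator: Discriminator | nn.Layer
    config: GANTrainConfig
    stage: str = ""
    history: dict[str, list[float]] = field(default_factory=dict)


def _build_default_models(config: GANTrainConfig, rng: np.random.Generator):
    gspec = GeneratorSpec(base_size=config.image_size, z_dim=config.z_dim,
                          width_factor=config.width_factor,
                          n_rdb=config.n_rdb, rdb_layers=config.rdb_layers,
                          rdb_growth=config.rdb_growth,
                          bn_momentum=config.bn_momentum)
    dspec = DiscriminatorSpec(base_size=config.image_size,
                              width_factor=config.width_factor,
                              leaky_alpha=config.leaky_alpha,
                              bn_momentum=config.bn_momentum)
    return Generator(gspec, rng), Discriminator(dspec, rng)


def train_gan(images: ImageSet, config: GANTrainConfig, stage: str = "",
              generator=None, discriminator=None,
              perceptual_extractor=None) -> GANBundle:
    """Alternating D/G training on one stage's images.

    Per iteration: one discriminator update on the cross-entropy loss plus
    ``lambda_gp`` times the gradient penalty, then one generator update on
    the adversarial loss plus ``lambda_perceptual`` times the perceptual
    loss.  The penalty's parameter gradient uses a central-difference
    directional surrogate along the frozen unit input-gradient (exact to
    O(ε²)); the recorded penalty value itself is exact.

    Fully reproducible from ``config.seed``.
    """
    if len(images) == 0:
        raise ValueError("cannot train a GAN on an empty dataset")
    rng = np.random.default_rng(config.seed)
    with nn.default_dtype(config.dtype):
        if generator is None or discriminator is None:
            g_built, d_built = _build_default_models(config, rng)
            generator = generator or g_built
            discriminator = discriminator or d_built
        if perceptual_extractor is None and config.lambda_perceptual > 0:
            perceptual_extractor = RandomConvFeatures()

    dtype = generator.params()[0].value.dtype
    x_all = np.asarray(images.pixels, dtype=dtype)
    n_data = len(x_all)
    bs = config.batch_size
    opt_d = nn.Adam(discriminator.params(), config.lr_d,
                    config.adam_beta1, config.adam_beta2)
    opt_g = nn.Adam(generator.params(), config.lr_g,
                    config.adam_beta1, config.adam_beta2)
    history: dict[str, list[float]] = {k: [] for k in
                                       ("iteration", "d_loss", "g_adv",
                                        "g_perceptual", "g_total", "gp",
                                        "d_real_mean", "d_fake_mean")}
    lam_p, lam_gp = config.lambda_perceptual, config.lambda_gp
    eps_fd = config.gp_fd_eps
    # frozen extractor: real-image features can be embedded once up front
    real_feats = None
    if lam_p > 0 and hasattr(perceptual_extractor, "net") and n_data <= 2048:
        real_feats = _feature_map(perceptual_extractor, x_all).copy()

    for it in range(config.iterations):
        idx = rng.integers(0, n_data, size=bs)
        real = x_all[idx]
        z = rng.standard_normal((bs, config.z_dim))
        fake = generator.forward(z, train=True)

        # ------------------------------------------------ discriminator step
        discriminator.zero_grad()
        gp_val = 0.0
        if lam_gp > 0:
            gp_val, xhat, dx, norms = _gradient_penalty_parts(
                discriminator, real, fake, rng)
            v = dx / np.maximum(norms, 1e-12).reshape(
                (-1,) + (1,) * (dx.ndim - 1))
            # surrogate s = (D(x̂+εv) − D(x̂−εv)) / 2ε ≈ ||∇D(x̂)||; both
            # shifted batches share one eval-mode pass (per-sample exact)
            both = np.concatenate([xhat + eps_fd * v, xhat - eps_fd * v])
            out = discriminator.forward(both, train=False)
            s = (out[:bs] - out[bs:]) / (2 * eps_fd)
            coeff = lam_gp * 2.0 * (s - 1.0) / (2 * eps_fd * bs)
            discriminator.backward(np.concatenate([coeff, -coeff]))

        d_real = discriminator.forward(real, train=True)
        dr = np.clip(d_real, _EPS, 1 - _EPS)
        discriminator.backward(-1.0 / (bs * dr))
        d_fake = discriminator.forward(fake, train=True)
        df = np.clip(d_fake, _EPS, 1 - _EPS)
        discriminator.backward(1.0 / (bs * (1 - df)))
        d_loss, _ = adversarial_losses(d_real, d_fake,
                                       saturating=config.saturating_g)
        opt_d.step()

        # ---------------------------------------------------- generator step
        z2 = rng.standard_normal((bs, config.z_dim))
        generator.zero_grad()
        discriminator.zero_grad()
        fake2 = generator.forward(z2, train=True)
        d_fake2 = discriminator.forward(fake2, train=True)
        df2 = np.clip(d_fake2, _EPS, 1 - _EPS)
        if config.saturating_g:
            g_adv = float(np.mean(np.log(1 - df2)))
            dprob = -1.0 / (bs * (1 - df2))
        else:
            g_adv = float(-np.mean(np.log(df2)))
            dprob = -1.0 / (bs * df2)
        dfake_pixels = discriminator.backward(dprob)
        g_perc = 0.0
        if lam_p > 0:
            g_perc, dperc = _perceptual_loss_and_grad(
                fake2, real, perceptual_extractor,
                real_features=None if real_feats is None else real_feats[idx])
            dfake_pixels = dfake_pixels + lam_p * dperc
        generator.backward(dfake_pixels)
        opt_g.step()
        discriminator.zero_grad()

        g_total = g_adv + lam_p * g_perc
        comps = LossComponents(d_loss=d_loss, g_adv=g_adv,
                               g_perceptual=g_perc, g_total=g_total,
                               gp=gp_val,
                               d_real_mean=float(np.mean(d_real)),
                               d_fake_mean=float(np.mean(d_fake)))
        if not comps.finite():
            raise DivergedError(it, "non-finite loss component")
        if it % config.log_every == 0 or it == config.iterations - 1:
            history["iteration"].append(float(it))
            history["d_loss"].append(comps.d_loss)
            history["g_adv"].append(comps.g_adv)
            history["g_perceptual"].append(comps.g_perceptual)
            history["g_total"].append(comps.g_total)
            history["gp"].append(comps.gp)
            history["d_real_mean"].append(comps.d_real_mean)
            history["d_fake_mean"].append(comps.d_fake_mean)

    return GANBundle(generator=generator, discriminator=discriminator,
                     config=config, stage=stage, history=history)


def sample_images(bundle: GANBundle, n: int, seed: int = 0) -> ImageSet:
    """Draw ``n`` generated images (provenance ``"generated"``, stage tag
    inherited from the bundle)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    size = bundle.config.image_size
    if n == 0:
        return ImageSet.empty((size, size))
    z = np.random.default_rng(seed).standard_normal((n, bundle.config.z_dim))
    pixels = bundle.generator.forward(z, train=False)
    stage = bundle.stage or "?"
    return ImageSet(pixels, np.full(n, stage, dtype=object),
                    np.full(n, GENERATED, dtype=object))


# ---------------------------------------------------------------------------
# checkpointing

def save_bundle(bundle: GANBundle, path: str | Path) -> None:
    """Single-file checkpoint: parameters + batch-norm state + config."""
    g_state = nn.get_state(bundle.generator)
    d_state = nn.get_state(bundle.discriminator)
    meta = {"config": asdict(bundle.config), "stage": bundle.stage,
            "history": bundle.history, "n_g": len(g_state)}
    arrays = {f"g{i}": a for i, a in enumerate(g_state)}
    arrays.update({f"d{i}": a for i, a in enumerate(d_state)})
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_bundle(path: str | Path) -> GANBundle:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        config = GANTrainConfig(**meta["config"])
        rng = np.random.default_rng(config.seed)
        with nn.default_dtype(config.dtype):
            generator, discriminator = _build_default_models(config, rng)
        n_g = meta["n_g"]
        g_state = [data[f"g{i}"] for i in range(n_g)]
        d_state = [data[f"d{i}"] for i in range(len(data.files) - 1 - n_g)]
        nn.set_state(generator, g_state)
        nn.set_state(discriminator, d_state)
    return GANBundle(generator=generator, discriminator=discriminator,
                     config=config, stage=meta["stage"],
                     history=meta["history"])
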