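"""Semi-supervised GAN with a K+1-class discriminator.

The discriminator is a residual convolutional classifier whose softmax has
K+1 entries: K real classes (healthy, unhealthy) plus one "fake" class for
generator output. Three signals train it each epoch, in the order
unlabeled -> labeled -> generated:

* an unsupervised real term ``-E log(1 - p(K+1|x))`` on unlabeled images,
* a supervised term ``-E log p(y|x, y<K+1)`` on the small labeled subset
  (the K+1 softmax restricted and renormalized to the K real classes),
* an unsupervised fake term on generated images — by default the standard
  ``-E log p(K+1|G(z))``; a ``log_free_fake_term`` flag switches to the
  log-free variant ``-E p(K+1|G(z))``.

The logged discriminator loss is the sum of its supervised and
unsupervised parts at every epoch. The generator is a five-layer
transposed-convolution network (batch norm + ReLU, tanh output) trained
purely by feature matching: it minimizes the squared distance between the
batch-mean discriminator features of real and generated images, where the
features are the interpretation layer — the fully connected layer between
the backbone and the K+1 logits, whose width can be tuned by linear
search.

Training runs for at most ``max_epochs`` epochs and stops early when the
validation error rate has not improved by more than ``min_delta`` for
``patience`` consecutive epochs; the best-validation checkpoint (weights
and batch-norm statistics) is kept.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from . import nn

logger = logging.getLogger("vetgan")

FAKE = "fake"  #: the (K+1)-th class


# ---------------------------------------------------------------------------
# Configuration and data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SGANConfig:
    """Architecture, optimizer and schedule settings.

    ``image_side`` must be a multiple of 16: the generator starts from a
    ``side/16`` seed map and doubles it through four stride-2 transposed
    convolutions before the stride-1 tanh output layer (five convolutional
    layers in total). ``stage_channels``/``blocks_per_stage`` describe the
    residual backbone; the production default (2, 2, 2, 2) blocks over
    (64, 128, 256, 512) channels is the classic 18-layer residual
    configuration, while desk-scale experiments use a narrower, shallower
    instance of the same family (see :func:`desk_scale_config`).
    """

    k: int = 2
    latent_dim: int = 100
    image_side: int = 256
    generator_channels: tuple[int, ...] = (512, 256, 128, 64, 32)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    interpretation_width: int = 128
    stem_stride: int = 2  #: classic residual nets downsample in the stem
    pretrained: bool = False
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10
    min_delta: float = 1e-4
    log_free_fake_term: bool = False
    generator_steps_every: int = 1  #: one generator step per this many unsup batches
    unsup_weight: float = 1.0       #: gradient weight of the unsupervised loss
    lr_decay_every: int = 0         #: halve-style decay period in epochs (0 = off)
    lr_decay_factor: float = 0.5
    warmup_epochs: int = 0          #: supervised-only epochs before adversarial phases
    generator_lr: float | None = None  #: generator Adam lr (None: same as lr)

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.image_side % 16 != 0:
            raise ValueError("image_side must be a multiple of 16")
        if not self.patience < self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if len(self.generator_channels) != 5:
            raise ValueError("generator_channels must list five layer widths")
        if len(self.stage_channels) != len(self.blocks_per_stage):
            raise ValueError("stage_channels and blocks_per_stage must align")


def desk_scale_config(image_side: int = 32, **overrides) -> SGANConfig:
    """A small configuration for CPU-scale experiments and tests."""
    base = dict(
        image_side=image_side,
        latent_dim=64,
        generator_channels=(64, 32, 24, 16, 12),
        stage_channels=(8, 16, 32),
        blocks_per_stage=(1, 1, 1),
        interpretation_width=32,
        batch_size=32,
    )
    base.update(overrides)
    return SGANConfig(**base)


@dataclass
class ImageSet:
    """A batch of 8-bit RGB images, optionally with binary labels."""

    images: np.ndarray                 #: (n, side, side, 3) uint8
    labels: np.ndarray | None = None   #: (n,) int in {0..K-1}, or None

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.images):
                raise ValueError("labels and images must have equal length")

    def __len__(self) -> int:
        return len(self.images)


@dataclass
class DiscriminatorOutput:
    class_logits: np.ndarray   #: (n, K+1)
    features: np.ndarray       #: (n, interpretation_width)


@dataclass
class TrainState:
    """Per-epoch loss history and early-stopping bookkeeping."""

    epochs: list[int] = field(default_factory=list)
    loss_supervised: list[float] = field(default_factory=list)
    loss_unsupervised: list[float] = field(default_factory=list)
    loss_discriminator: list[float] = field(default_factory=list)
    loss_generator: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    def history_rows(self) -> list[dict]:
        return [
            {
                "epoch": e,
                "loss_supervised": ls,
                "loss_unsupervised": lu,
                "loss_discriminator": ld,
                "loss_generator": lg,
                "val_loss": vl,
                "val_accuracy": va,
            }
            for e, ls, lu, ld, lg, vl, va in zip(
                self.epochs,
                self.loss_supervised,
                self.loss_unsupervised,
                self.loss_discriminator,
                self.loss_generator,
                self.val_loss,
                self.val_accuracy,
            )
        ]


class EarlyStopping:
    """Stop when the monitored loss fails to improve for ``patience`` epochs.

    ``update`` returns True on the epoch at which training should stop;
    with patience 10 and no improvement after the first epoch, that is
    epoch 11.
    """

    def __init__(self, patience: int = 10, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = 0
        self.since_improvement = 0
        self.epoch = 0

    def update(self, loss: float) -> bool:
        self.epoch += 1
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = self.epoch
            self.since_improvement = 0
        else:
            self.since_improvement += 1
        return self.since_improvement >= self.patience


# ---------------------------------------------------------------------------
# Pixel scaling
# ---------------------------------------------------------------------------

def to_network(images: np.ndarray) -> np.ndarray:
    """Map uint8 NHWC images to float32 in [-1, 1] (tanh range)."""
    return (np.asarray(images, dtype=np.float32) / 127.5 - 1.0)


def from_network(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`to_network`, rounding back to uint8."""
    imgs = (np.asarray(x, dtype=np.float32) + 1.0) * 127.5
    return np.clip(np.round(imgs), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

class Generator:
    """z -> image tensor in [-1, 1] via five convolutional layers."""

    def __init__(self, config: SGANConfig, rng: np.random.Generator):
        c0, c1, c2, c3, c4 = config.generator_channels
        s0 = config.image_side // 16
        self.latent_dim = config.latent_dim
        self.net = nn.Sequential(
            nn.Dense(config.latent_dim, s0 * s0 * c0, rng),
            nn.Reshape((s0, s0, c0)),
            nn.BatchNorm2d(c0),
            nn.ReLU(),
            nn.ConvTranspose2d(c0, c1, 4, 2, 1, rng),   # s0 -> 2 s0
            nn.BatchNorm2d(c1),
            nn.ReLU(),
            nn.ConvTranspose2d(c1, c2, 4, 2, 1, rng),   # -> 4 s0
            nn.BatchNorm2d(c2),
            nn.ReLU(),
            nn.ConvTranspose2d(c2, c3, 4, 2, 1, rng),   # -> 8 s0
            nn.BatchNorm2d(c3),
            nn.ReLU(),
            nn.ConvTranspose2d(c3, c4, 4, 2, 1, rng),   # -> 16 s0 = image_side
            nn.BatchNorm2d(c4),
            nn.ReLU(),
            nn.Conv2d(c4, 3, 3, 1, 1, rng),
            nn.Tanh(),
        )

    def params(self) -> list[nn.Param]:
        return self.net.params()

    def forward(self, z: np.ndarray, train: bool = True) -> np.ndarray:
        return self.net.forward(np.asarray(z, dtype=np.float32), train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)


class Discriminator:
    """Residual backbone -> interpretation layer -> K+1 logits."""

    def __init__(self, config: SGANConfig, rng: np.random.Generator):
        if config.pretrained:
            raise NotImplementedError(
                "pretrained backbone weights are not bundled; "
                "set pretrained=False to train from random initialization"
            )
        channels = config.stage_channels
        layers: list[nn.Module] = [
            nn.Conv2d(3, channels[0], 3, config.stem_stride, 1, rng),
            nn.BatchNorm2d(channels[0]),
            nn.ReLU(),
        ]
        cin = channels[0]
        for i, (cout, n_blocks) in enumerate(zip(channels, config.blocks_per_stage)):
            for b in range(n_blocks):
                stride = 2 if (i > 0 and b == 0) else 1
                layers.append(nn.ResidualBlock(cin, cout, stride, rng))
                cin = cout
        self.backbone = nn.Sequential(*layers)
        self.pool = nn.GlobalAvgPool()
        self.interp = nn.Dense(cin, config.interpretation_width, rng)
        self.interp_act = nn.ReLU()
        self.head = nn.Dense(config.interpretation_width, config.k + 1, rng)
        self.k = config.k

    def params(self) -> list[nn.Param]:
        return (
            self.backbone.params()
            + self.pool.params()
            + self.interp.params()
            + self.head.params()
        )

    def forward(self, x: np.ndarray, train: bool = True) -> DiscriminatorOutput:
        h = self.backbone.forward(np.asarray(x, dtype=np.float32), train)
        h = self.pool.forward(h, train)
        features = self.interp_act.forward(self.interp.forward(h, train), train)
        logits = self.head.forward(features, train)
        return DiscriminatorOutput(class_logits=logits, features=features)

    def backward(
        self,
        dlogits: np.ndarray | None = None,
        dfeatures: np.ndarray | None = None,
    ) -> np.ndarray:
        """Backpropagate from the logits and/or the feature layer to the input."""
        if dlogits is None and dfeatures is None:
            raise ValueError("nothing to backpropagate")
        dfeat = 0.0 if dfeatures is None else np.asarray(dfeatures, dtype=np.float32)
        if dlogits is not None:
            dfeat = dfeat + self.head.backward(np.asarray(dlogits, dtype=np.float32))
        dh = self.interp.backward(self.interp_act.backward(dfeat))
        dh = self.pool.backward(dh)
        return self.backbone.backward(dh)


def build_generator(config: SGANConfig, seed: int = 0) -> Generator:
    return Generator(config, np.random.default_rng(seed))


def build_discriminator(config: SGANConfig, seed: int = 0) -> Discriminator:
    return Discriminator(config, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# Losses (values and analytic gradients w.r.t. the logits/features)
# ---------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _supervised_grad(logits: np.ndarray, labels: np.ndarray, k: int):
    """-mean log q(y|x) with q the softmax renormalized to the K real classes."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k - 1}]")
    m = len(labels)
    real = logits[:, :k]
    loss = float(np.mean(logsumexp(real, axis=1) - real[np.arange(m), labels]))
    q = _softmax(real)
    grad = np.zeros_like(logits)
    grad[:, :k] = q
    grad[np.arange(m), labels] -= 1.0
    return loss, grad / m


def _unsup_real_grad(logits: np.ndarray, k: int):
    """-mean log(1 - p(fake|x)) on real images."""
    m = len(logits)
    lse_all = logsumexp(logits, axis=1)
    lse_real = logsumexp(logits[:, :k], axis=1)
    loss = float(np.mean(lse_all - lse_real))
    p = _softmax(logits)
    q = _softmax(logits[:, :k])
    grad = p.copy()
    grad[:, :k] -= q
    return loss, grad / m


def _unsup_fake_grad(logits: np.ndarray, k: int, log_free_fake_term: bool):
    """Fake-image term: -mean log p(fake|G(z)), or -mean p(fake|G(z)) verbatim."""
    m = len(logits)
    p = _softmax(logits)
    if log_free_fake_term:
        loss = float(-np.mean(p[:, k]))
        grad = p[:, k : k + 1] * p
        grad[:, k] -= p[:, k]
        return loss, grad / m
    lse_all = logsumexp(logits, axis=1)
    loss = float(np.mean(lse_all - logits[:, k]))
    grad = p.copy()
    grad[:, k] -= 1.0
    return loss, grad / m


def _feature_matching_grad(real_features: np.ndarray, fake_features: np.ndarray):
    """||mean f(x) - mean f(G(z))||_2^2 and its gradient w.r.t. fake features."""
    real_features = np.asarray(real_features, dtype=np.float64)
    fake_features = np.asarray(fake_features, dtype=np.float64)
    if real_features.shape[1] != fake_features.shape[1]:
        raise ValueError("feature dimensionality mismatch")
    diff = real_features.mean(axis=0) - fake_features.mean(axis=0)
    loss = float(diff @ diff)
    grad = np.broadcast_to(
        -2.0 * diff / len(fake_features), fake_features.shape
    ).astype(np.float32)
    return loss, grad


def supervised_loss(outputs: DiscriminatorOutput, labels: np.ndarray, k: int = 2) -> float:
    """Mean negative log-probability of the true class among the K real classes."""
    loss, _ = _supervised_grad(outputs.class_logits, labels, k)
    return loss


def unsupervised_loss(
    real_outputs: DiscriminatorOutput,
    fake_outputs: DiscriminatorOutput,
    k: int = 2,
    log_free_fake_term: bool = False,
) -> float:
    """Real-vs-fake discrimination loss over one real and one fake batch."""
    if not len(real_outputs.class_logits) or not len(fake_outputs.class_logits):
        raise ValueError("both batches must be nonempty")
    real_term, _ = _unsup_real_grad(real_outputs.class_logits, k)
    fake_term, _ = _unsup_fake_grad(fake_outputs.class_logits, k, log_free_fake_term)
    return real_term + fake_term


def feature_matching_loss(real_features: np.ndarray, fake_features: np.ndarray) -> float:
    """Squared L2 distance between batch-mean features."""
    loss, _ = _feature_matching_grad(real_features, fake_features)
    return loss


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class SGANModel:
    generator: Generator
    discriminator: Discriminator
    config: SGANConfig
    seed: int
    state: TrainState | None = None

    @property
    def trained(self) -> bool:
        return self.state is not None


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    perm = rng.permutation(n)
    for start in range(0, n, batch_size):
        idx = perm[start : start + batch_size]
        if len(idx) >= 2:  # batch norm needs more than one sample
            yield idx


def _validation_scores(
    disc: Discriminator, x_val: np.ndarray, y_val: np.ndarray, k: int, batch_size: int
) -> tuple[float, float]:
    losses, correct, total = [], 0, 0
    for start in range(0, len(x_val), batch_size):
        xb = x_val[start : start + batch_size]
        yb = y_val[start : start + batch_size]
        out = disc.forward(xb, train=False)
        loss, _ = _supervised_grad(out.class_logits, yb, k)
        losses.append(loss * len(xb))
        correct += int(np.sum(out.class_logits[:, :k].argmax(axis=1) == yb))
        total += len(xb)
    return float(np.sum(losses) / total), correct / total


def train(
    labeled: ImageSet,
    unlabeled: ImageSet,
    validation: ImageSet,
    config: SGANConfig,
    seed: int = 0,
) -> SGANModel:
    """Train the SGAN; returns the model restored to its best checkpoint.

    Each epoch performs, in order: unsupervised discriminator steps over
    the unlabeled pool (paired with fresh generated batches), supervised
    steps over the labeled subset, and feature-matching generator steps.
    """
    if labeled.labels is None or len(labeled) == 0:
        raise ValueError("labeled set must be nonempty and carry labels")
    present = np.unique(labeled.labels)
    if len(present) < config.k:
        raise ValueError(
            f"labeled set must contain every class; found only {present.tolist()}"
        )
    if validation.labels is None:
        raise ValueError("validation set must carry labels")

    rng = np.random.default_rng(seed)
    gen = Generator(config, rng)
    disc = Discriminator(config, rng)
    g_lr = config.lr if config.generator_lr is None else config.generator_lr
    opt_g = nn.Adam(gen.params(), g_lr, config.betas)
    opt_d = nn.Adam(disc.params(), config.lr, config.betas)

    x_lab = to_network(labeled.images)
    y_lab = labeled.labels
    x_unl = to_network(unlabeled.images)
    x_val = to_network(validation.images)
    y_val = validation.labels
    k, m = config.k, config.batch_size

    state = TrainState()
    # "no additional learning" is monitored on the validation error rate:
    # under adversarial feature drift the supervised validation loss can
    # rise from miscalibration alone while classification keeps improving
    stopper = EarlyStopping(config.patience, config.min_delta)
    best_params = (nn.get_state(disc), nn.get_state(gen))

    for epoch in range(1, config.max_epochs + 1):
        if config.lr_decay_every and epoch > 1 and (epoch - 1) % config.lr_decay_every == 0:
            opt_d.lr *= config.lr_decay_factor
            opt_g.lr *= config.lr_decay_factor

        in_warmup = epoch <= config.warmup_epochs

        # (i) unsupervised: real unlabeled batches vs generated fakes
        unsup_losses, gen_losses = [], []
        unsup_batches = list(_iter_batches(len(x_unl), m, rng))
        for idx in unsup_batches if not in_warmup else []:
            xb = x_unl[idx]
            z = rng.standard_normal((len(idx), config.latent_dim)).astype(np.float32)
            fake = gen.forward(z, train=True)

            opt_d.zero_grad()
            out_real = disc.forward(xb, train=True)
            loss_real, dreal = _unsup_real_grad(out_real.class_logits, k)
            disc.backward(dlogits=config.unsup_weight * dreal)
            with nn.frozen_batchnorm_stats():
                out_fake = disc.forward(fake, train=True)
            loss_fake, dfake = _unsup_fake_grad(
                out_fake.class_logits, k, config.log_free_fake_term
            )
            disc.backward(dlogits=config.unsup_weight * dfake)
            opt_d.step()
            unsup_losses.append(loss_real + loss_fake)

        # (ii) supervised: labeled batches, resampled to as many steps as the
        # unsupervised phase so the small labeled subset is not drowned out
        sup_losses = []
        n_sup_steps = max(len(unsup_batches), 1)
        batch_lab = min(m, len(x_lab))
        for _ in range(n_sup_steps):
            idx = rng.choice(len(x_lab), size=batch_lab, replace=False)
            opt_d.zero_grad()
            out = disc.forward(x_lab[idx], train=True)
            loss, dlog = _supervised_grad(out.class_logits, y_lab[idx], k)
            disc.backward(dlogits=dlog)
            opt_d.step()
            sup_losses.append(loss)

        # (iii) generator: feature matching against fresh fakes
        for step, idx in enumerate(unsup_batches if not in_warmup else []):
            if step % config.generator_steps_every:
                continue
            xb = x_unl[idx]
            out_real = disc.forward(xb, train=True)
            f_real = out_real.features.copy()
            z = rng.standard_normal((len(idx), config.latent_dim)).astype(np.float32)
            fake = gen.forward(z, train=True)
            with nn.frozen_batchnorm_stats():
                out_fake = disc.forward(fake, train=True)
            loss_g, dff = _feature_matching_grad(f_real, out_fake.features)
            opt_g.zero_grad()
            opt_d.zero_grad()  # D grads from this pass are discarded
            dx = disc.backward(dfeatures=dff)
            gen.backward(dx)
            opt_g.step()
            gen_losses.append(loss_g)

        l_sup = float(np.mean(sup_losses)) if sup_losses else 0.0
        l_unsup = float(np.mean(unsup_losses)) if unsup_losses else 0.0
        l_gen = float(np.mean(gen_losses)) if gen_losses else 0.0
        val_loss, val_acc = _validation_scores(disc, x_val, y_val, k, m)

        state.epochs.append(epoch)
        state.loss_supervised.append(l_sup)
        state.loss_unsupervised.append(l_unsup)
        state.loss_discriminator.append(l_sup + l_unsup)
        state.loss_generator.append(l_gen)
        state.val_loss.append(val_loss)
        state.val_accuracy.append(val_acc)

        stop = stopper.update(1.0 - val_acc)
        if stopper.since_improvement == 0:
            best_params = (nn.get_state(disc), nn.get_state(gen))
        logger.debug(
            "epoch %d: L_sup=%.4f L_unsup=%.4f L_G=%.4f val=%.4f acc=%.3f",
            epoch, l_sup, l_unsup, l_gen, val_loss, val_acc,
        )
        if stop:
            break

    state.best_epoch = stopper.best_epoch
    state.stopped_epoch = stopper.epoch
    nn.set_state(disc, best_params[0])
    nn.set_state(gen, best_params[1])
    return SGANModel(generator=gen, discriminator=disc, config=config, seed=seed, state=state)


def train_supervised_baseline(
    labeled: ImageSet,
    validation: ImageSet,
    config: SGANConfig,
    seed: int = 0,
) -> SGANModel:
    """Supervised-only reference: same discriminator, labeled data only.

    No generator and no unsupervised term — this is the control against
    which the semi-supervised advantage is measured.
    """
    if labeled.labels is None or len(labeled) == 0:
        raise ValueError("labeled set must be nonempty and carry labels")
    rng = np.random.default_rng(seed)
    gen = Generator(config, rng)  # built for interface parity; never trained
    disc = Discriminator(config, rng)
    opt_d = nn.Adam(disc.params(), config.lr, config.betas)

    x_lab = to_network(labeled.images)
    y_lab = labeled.labels
    x_val = to_network(validation.images)
    y_val = validation.labels
    k, m = config.k, config.batch_size

    state = TrainState()
    stopper = EarlyStopping(config.patience, config.min_delta)
    best = nn.get_state(disc)
    for epoch in range(1, config.max_epochs + 1):
        sup_losses = []
        for idx in _iter_batches(len(x_lab), m, rng):
            opt_d.zero_grad()
            out = disc.forward(x_lab[idx], train=True)
            loss, dlog = _supervised_grad(out.class_logits, y_lab[idx], k)
            disc.backward(dlogits=dlog)
            opt_d.step()
            sup_losses.append(loss)
        val_loss, val_acc = _validation_scores(disc, x_val, y_val, k, m)
        l_sup = float(np.mean(sup_losses)) if sup_losses else 0.0
        state.epochs.append(epoch)
        state.loss_supervised.append(l_sup)
        state.loss_unsupervised.append(0.0)
        state.loss_discriminator.append(l_sup)
        state.loss_generator.append(0.0)
        state.val_loss.append(val_loss)
        state.val_accuracy.append(val_acc)
        stop = stopper.update(1.0 - val_acc)
        if stopper.since_improvement == 0:
            best = nn.get_state(disc)
        if stop:
            break
    state.best_epoch = stopper.best_epoch
    state.stopped_epoch = stopper.epoch
    nn.set_state(disc, best)
    return SGANModel(generator=gen, discriminator=disc, config=config, seed=seed, state=state)


def predict(model: SGANModel, images: np.ndarray, batch_size: int = 64):
    """Class probabilities over the K real classes plus the fake probability.

    Returns ``(class_probs, fake_probs)``: the first K softmax entries
    renormalized, and the mass on the fake class. The predicted label is
    ``class_probs.argmax(axis=1)``.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    x = to_network(images)
    k = model.config.k
    probs, fakes = [], []
    for start in range(0, len(x), batch_size):
        out = model.discriminator.forward(x[start : start + batch_size], train=False)
        p = _softmax(out.class_logits)
        real = p[:, :k]
        probs.append(real / real.sum(axis=1, keepdims=True))
        fakes.append(p[:, k])
    return np.concatenate(probs), np.concatenate(fakes)


def save_checkpoint(model: SGANModel, path) -> None:
    """Persist weights, batch-norm statistics, config, seed and history."""
    import json as _json
    from pathlib import Path as _Path

    path = _Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": dataclasses.asdict(model.config),
        "seed": model.seed,
        "history": model.state.history_rows() if model.state else [],
        "best_epoch": model.state.best_epoch if model.state else 0,
        "stopped_epoch": model.state.stopped_epoch if model.state else 0,
    }
    disc_state = nn.get_state(model.discriminator)
    gen_state = nn.get_state(model.generator)
    arrays = {f"d_{i}": a for i, a in enumerate(disc_state)}
    arrays.update({f"g_{i}": a for i, a in enumerate(gen_state)})
    np.savez(path, meta=_json.dumps(meta), **arrays)


def load_checkpoint(path) -> SGANModel:
    """Rebuild a trained model from :func:`save_checkpoint` output."""
    import json as _json

    with np.load(path, allow_pickle=False) as data:
        meta = _json.loads(str(data["meta"]))
        raw = dict(meta["config"])
        for key in ("generator_channels", "stage_channels", "blocks_per_stage", "betas"):
            raw[key] = tuple(raw[key])
        config = SGANConfig(**raw)
        rng = np.random.default_rng(meta["seed"])
        gen = Generator(config, rng)
        disc = Discriminator(config, rng)
        d_keys = sorted((k for k in data.files if k.startswith("d_")),
                        key=lambda s: int(s[2:]))
        g_keys = sorted((k for k in data.files if k.startswith("g_")),
                        key=lambda s: int(s[2:]))
        nn.set_state(disc, [data[k] for k in d_keys])
        nn.set_state(gen, [data[k] for k in g_keys])
    state = TrainState()
    for row in meta["history"]:
        state.epochs.append(row["epoch"])
        state.loss_supervised.append(row["loss_supervised"])
        state.loss_unsupervised.append(row["loss_unsupervised"])
        state.loss_discriminator.append(row["loss_discriminator"])
        state.loss_generator.append(row["loss_generator"])
        state.val_loss.append(row["val_loss"])
        state.val_accuracy.append(row["val_accuracy"])
    state.best_epoch = meta["best_epoch"]
    state.stopped_epoch = meta["stopped_epoch"]
    return SGANModel(generator=gen, discriminator=disc, config=config,
                     seed=meta["seed"], state=state)


#: desk-scale schedule/architecture overrides used by the packaged
#: benchmark and as the pipeline's small-image training defaults
BENCHMARK_OVERRIDES: dict = dict(
    stage_channels=(12, 24, 48),
    interpretation_width=64,
    max_epochs=35,
    patience=12,
    lr=1e-3,
    lr_decay_every=10,
    unsup_weight=0.5,
    batch_size=64,
    generator_steps_every=2,
)


def benchmark_config() -> SGANConfig:
    """The desk-scale configuration used for the synthetic benchmark."""
    return desk_scale_config(**BENCHMARK_OVERRIDES)


def run_synthetic_benchmark(
    seed: int,
    n_train: int = 600,
    n_val: int = 100,
    n_test: int = 200,
    labeled_fraction: float = 0.1,
    image_side: int = 32,
    augment_per_labeled: int = 2,
    config: SGANConfig | None = None,
) -> dict:
    """Semi-supervised vs. supervised-only comparison on synthetic data.

    Generates a training pool (10% labeled by default), a labeled
    validation set for early stopping and a held-out test set; trains the
    SGAN and the supervised-only baseline on the same labeled subset; and
    returns held-out accuracies plus the trained models' histories.

    The labeled subset is expanded by ``augment_per_labeled`` offline
    geometric augmentations per image — the pipeline's standard remedy
    for the tiny-labeled-set regime, where the discriminator otherwise
    memorizes the handful of labeled originals within a few epochs. Both
    the SGAN and the supervised-only control see the identical augmented
    labeled set, so the comparison isolates the unlabeled-data advantage.
    """
    from . import metrics as _metrics
    from .augment import apply_plan, sample_plan
    from .synthetic_data import SynthSpec, generate

    if config is None:
        config = benchmark_config()
    ss = np.random.SeedSequence(seed)
    s_train, s_val, s_test, s_model, s_aug = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(5)
    )
    train_ds = generate(SynthSpec(n_images=n_train, image_side=image_side,
                                  labeled_fraction=labeled_fraction, seed=s_train))
    val_ds = generate(SynthSpec(n_images=n_val, image_side=image_side,
                                labeled_fraction=1.0, seed=s_val))
    test_ds = generate(SynthSpec(n_images=n_test, image_side=image_side,
                                 labeled_fraction=1.0, seed=s_test))

    lab_images = train_ds.images[train_ds.labeled_indices]
    lab_labels = train_ds.labels[train_ds.labeled_indices]
    if augment_per_labeled > 0:
        aug_rng = np.random.default_rng(s_aug)
        extra_images, extra_labels = [], []
        for img, label in zip(lab_images, lab_labels):
            for _ in range(augment_per_labeled):
                extra_images.append(apply_plan(img, sample_plan(aug_rng)))
                extra_labels.append(label)
        lab_images = np.concatenate([lab_images, np.stack(extra_images)])
        lab_labels = np.concatenate([lab_labels, np.array(extra_labels)])
    labeled = ImageSet(lab_images, lab_labels)
    unlabeled = ImageSet(train_ds.images[train_ds.unlabeled_indices])
    validation = ImageSet(val_ds.images, val_ds.labels)

    model = train(labeled, unlabeled, validation, config, seed=s_model)
    baseline = train_supervised_baseline(labeled, validation, config, seed=s_model)

    results = {}
    for name, mdl in (("sgan", model), ("baseline", baseline)):
        probs, _ = predict(mdl, test_ds.images)
        pred = probs.argmax(axis=1)
        summ = _metrics.summary(_metrics.confusion(pred, test_ds.labels))
        summ["auc_roc"] = _metrics.auc_roc(probs[:, 1], test_ds.labels)
        results[name] = summ
    return {
        "seed": seed,
        "n_labeled": len(labeled),
        "n_unlabeled": len(unlabeled),
        "sgan": results["sgan"],
        "baseline": results["baseline"],
        "sgan_model": model,
        "baseline_model": baseline,
    }


def search_interpretation_width(
    candidates: Sequence[int],
    labeled: ImageSet,
    unlabeled: ImageSet,
    validation: ImageSet,
    config: SGANConfig,
    seed: int = 0,
    search_epochs: int = 5,
) -> tuple[int, dict[int, float]]:
    """Linear search over interpretation-layer widths.

    Trains one short-budget model per candidate width and returns the
    width with the best validation accuracy (ties go to the smaller
    width) along with the per-width scores.
    """
    if not candidates:
        raise ValueError("candidate width list must be nonempty")
    scores: dict[int, float] = {}
    for width in sorted(candidates):
        cfg = replace(
            config,
            interpretation_width=int(width),
            max_epochs=search_epochs,
            patience=search_epochs - 1,
        )
        model = train(labeled, unlabeled, validation, cfg, seed=seed)
        scores[int(width)] = model.state.val_accuracy[model.state.best_epoch - 1]
    return _select_best_width(scores), scores


def _select_best_width(scores: dict[int, float]) -> int:
    """Highest validation accuracy; ties broken toward the smaller width."""
    return min(scores, key=lambda w: (-scores[w], w))
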