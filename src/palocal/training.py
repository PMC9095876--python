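"""Adversarial training of the sparse-to-dense generators.

Loss functions
--------------
The discriminator maximizes E[log D(y)] + E[log(1 - D(G(x)))] (the min-max
objective); the generator minimizes, depending on the stage:

* 3D OR-PAM:          L = 0.01 * MAE(y, G(x)) - log D(G(x))
* 2D pre-training:    L = 0.3  * MAE + 0.7  * (1 - MSSSIM(y, G(x)))
* 2D fine-tuning:     L = 0.03 * MAE + 0.07 * (1 - MSSSIM) - log D(G(x))

where MAE is the mean absolute error over the N pixels of the image and
MSSSIM the multiscale structural similarity. The 2D network is first
pre-trained on OR-PAM maximum-amplitude-projection images and then fine-tuned
on the (smaller) PACT dataset with a fresh discriminator — transfer learning
across the two angiographic domains.

Checkpointing keeps the epoch with the highest validation MS-SSIM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .grad import Tensor, Adam, avg_pool_nd, conv_nd
from .metrics import (MetricConfig, gaussian_window_1d, max_feasible_scales,
                      ms_ssim)
from .networks import (GeneratorSpec, UNetGenerator, PatchDiscriminator,
                       DiscriminatorSpec, build_discriminator)

logger = logging.getLogger(__name__)

__all__ = [
    "PairedSample", "TrainConfig", "TrainingRecord",
    "loss_generator_3d", "loss_pretrain_2d", "loss_generator_2d",
    "loss_discriminator", "ms_ssim_tensor", "augment", "fit",
    "transfer_finetune",
]

_PROB_EPS = 1e-7  # probability clamp before logarithms


@dataclass
class PairedSample:
    """One training pair: generator input x and dense target y.

    `x` has shape (C, *spatial) — two channels (sparse localization +
    regular image) for the 3D network, one (sparse localization) for 2D —
    and `y` has shape (1, *spatial), both normalized to [0, 1].
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.x.shape[1:] != self.y.shape[1:]:
            raise ValueError("x and y must be spatially aligned")
        for a in (self.x, self.y):
            if a.min() < 0 or a.max() > 1:
                raise ValueError("samples must be normalized to [0, 1]")

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.x.shape[1:]


@dataclass
class TrainConfig:
    """Optimization and augmentation settings."""

    epochs: int = 200
    loss: str = "2d_pretrain"  # "3d" | "2d_pretrain" | "2d_adversarial"
    lr: float = 2e-4
    betas: tuple[float, float] = (0.5, 0.999)
    weight_decay: float = 1e-5  # L2 regularization coefficient
    batch_size: int = 8
    crop: tuple[int, ...] | None = None
    flip_prob: float = 0.5
    seed: int = 0
    dtype: str = "float32"  # compute precision of the optimization
    metric_config: MetricConfig = field(default_factory=MetricConfig)

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.loss not in ("3d", "2d_pretrain", "2d_adversarial"):
            raise ValueError(f"unknown loss '{self.loss}'")

    @property
    def adversarial(self) -> bool:
        return self.loss in ("3d", "2d_adversarial")


@dataclass
class TrainingRecord:
    """Per-epoch bookkeeping plus the best (highest validation MS-SSIM) state."""

    epochs: list[dict] = field(default_factory=list)
    loss_name: str = ""
    best_epoch: int = -1
    best_val_msssim: float = -np.inf
    best_state: list | None = None
    aborted: bool = False
    diagnostic: str = ""


# ---------------------------------------------------------------------------
# differentiable MS-SSIM (mirrors palocal.metrics on the autodiff path)
# ---------------------------------------------------------------------------

def _gaussian_kernel_nd(shape, config: MetricConfig) -> np.ndarray:
    wins = []
    for n in shape:
        size = min(config.win_size, n if n % 2 == 1 else n - 1)
        wins.append(gaussian_window_1d(size, config.win_sigma))
    k = wins[0]
    for w in wins[1:]:
        k = np.multiply.outer(k, w)
    return k[None, None]  # (1, 1, *K)


def _ssim_components_tensor(a: Tensor, b: Tensor, kern: Tensor,
                            config: MetricConfig):
    g = lambda t: conv_nd(t, kern, None, stride=1, pad=0)  # valid Gaussian filtering
    mu_a, mu_b = g(a), g(b)
    var_a = g(a * a) - mu_a * mu_a
    var_b = g(b * b) - mu_b * mu_b
    cov = g(a * b) - mu_a * mu_b
    c1, c2 = config.c1, config.c2
    lum = (mu_a * mu_b * 2.0 + c1) / (mu_a * mu_a + mu_b * mu_b + c1)
    cs = (cov * 2.0 + c2) / (var_a + var_b + c2)
    return (lum * cs).mean(), cs.mean()


def ms_ssim_tensor(a: Tensor, b: Tensor, config: MetricConfig | None = None) -> Tensor:
    """Differentiable MS-SSIM of (B, 1, *spatial) tensors.

    Same construction as :func:`palocal.metrics.ms_ssim`; contrast-structure
    means are clamped to a small positive floor so fractional powers stay
    differentiable.
    """
    config = config or MetricConfig()
    spatial = a.shape[2:]
    feasible = max_feasible_scales(spatial, config)
    if feasible < 1:
        raise ValueError(f"window does not fit spatial shape {spatial}")
    n_scales = min(5, feasible) if config.scales is None else config.scales
    if n_scales > feasible:
        raise ValueError(f"requested {config.scales} scales infeasible; "
                         f"maximum feasible scale count is {feasible}")
    weights = np.asarray(config.weights[:n_scales], dtype=float)
    weights = weights / weights.sum()
    score = None
    for j in range(n_scales):
        kern = Tensor(_gaussian_kernel_nd(a.shape[2:], config).astype(a.data.dtype))
        s, cs = _ssim_components_tensor(a, b, kern, config)
        term = (s if j == n_scales - 1 else cs).clip(1e-6, 1.0) ** float(weights[j])
        score = term if score is None else score * term
        if j < n_scales - 1:
            a, b = avg_pool_nd(a, 2), avg_pool_nd(b, 2)
    return score


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _as_tensor(v) -> Tensor:
    return v if isinstance(v, Tensor) else Tensor(np.asarray(v, dtype=np.float64))


def _check_prob(d_prob) -> Tensor:
    p = _as_tensor(d_prob)
    if p.data.size == 1 and not isinstance(d_prob, Tensor):
        if not 0.0 < float(p.data) < 1.0:
            raise ValueError("discriminator probability must lie in (0, 1)")
    return p.clip(_PROB_EPS, 1.0 - _PROB_EPS)


def _mae(y: Tensor, g_out: Tensor, pixel_count: int | None) -> Tensor:
    diff = (y - g_out).abs()
    if pixel_count is None:
        return diff.mean()
    return diff.sum() / float(pixel_count)


def loss_generator_3d(y, g_out, d_prob, pixel_count: int | None = None) -> Tensor:
    """3D generator loss: 0.01 * MAE - log D(G(x))."""
    y, g_out = _as_tensor(y), _as_tensor(g_out)
    return 0.01 * _mae(y, g_out, pixel_count) + (-(_check_prob(d_prob).log()))


def loss_pretrain_2d(y, g_out, pixel_count: int | None = None,
                     metric_config: MetricConfig | None = None) -> Tensor:
    """2D transfer-learning pre-training loss: 0.3 * MAE + 0.7 * (1 - MSSSIM)."""
    y, g_out = _as_tensor(y), _as_tensor(g_out)
    ya, ga = _batched(y), _batched(g_out)
    return (0.3 * _mae(y, g_out, pixel_count)
            + 0.7 * (1.0 - ms_ssim_tensor(ya, ga, metric_config)))


def loss_generator_2d(y, g_out, d_prob, pixel_count: int | None = None,
                      metric_config: MetricConfig | None = None) -> Tensor:
    """2D fine-tuning loss: 0.03 * MAE + 0.07 * (1 - MSSSIM) - log D(G(x))."""
    y, g_out = _as_tensor(y), _as_tensor(g_out)
    ya, ga = _batched(y), _batched(g_out)
    return (0.03 * _mae(y, g_out, pixel_count)
            + 0.07 * (1.0 - ms_ssim_tensor(ya, ga, metric_config))
            + (-(_check_prob(d_prob).log())))


def loss_discriminator(d_real_prob, d_fake_prob) -> Tensor:
    """Discriminator loss: -[log D(y) + log(1 - D(G(x)))]."""
    pr = _check_prob(d_real_prob)
    pf = _check_prob(d_fake_prob)
    return -(pr.log()) - ((1.0 - pf).log())


def _batched(t: Tensor) -> Tensor:
    """Reshape (..., *spatial) to (B, 1, *spatial) for the metric path."""
    if t.ndim >= 4:  # already batched with channel axis
        return t
    if t.ndim == 3 and t.shape[0] == 1:  # (1, H, W) single channel image
        return t.reshape((1,) + t.shape)
    return t.reshape((1, 1) + t.shape)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(sample: PairedSample, crop: tuple[int, ...] | None,
            flip_prob: float, rng: np.random.Generator) -> PairedSample:
    """Random crop + random x/y flips, applied identically to x and y."""
    x, y = sample.x, sample.y
    spatial = x.shape[1:]
    if crop is not None:
        if len(crop) != len(spatial):
            raise ValueError("crop rank must match sample rank")
        if any(c > n for c, n in zip(crop, spatial)):
            raise ValueError(f"crop {crop} larger than sample {spatial}")
        origins = [rng.integers(0, n - c + 1) for c, n in zip(crop, spatial)]
        sl = (slice(None),) + tuple(slice(o, o + c) for o, c in zip(origins, crop))
        x, y = x[sl], y[sl]
    # flips only in the lateral (x, y) axes — never the axial axis
    for ax in (1, 2):  # array axes of x/y spatial dims (axis 0 is channels)
        if ax - 1 < min(2, len(spatial)) and rng.random() < flip_prob:
            x = np.flip(x, axis=ax)
            y = np.flip(y, axis=ax)
    return PairedSample(x.copy(), y.copy())


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _batch_tensors(samples: list[PairedSample],
                   dtype=np.float32) -> tuple[Tensor, Tensor]:
    x = Tensor(np.stack([s.x for s in samples]).astype(dtype))
    y = Tensor(np.stack([s.y for s in samples]).astype(dtype))
    return x, y


def _generator_loss(config: TrainConfig, y: Tensor, g_out: Tensor,
                    d_prob: Tensor | None) -> Tensor:
    if config.loss == "3d":
        return loss_generator_3d(y, g_out, d_prob)
    if config.loss == "2d_pretrain":
        return loss_pretrain_2d(y, g_out, metric_config=config.metric_config)
    return loss_generator_2d(y, g_out, d_prob, metric_config=config.metric_config)


def validate(generator: UNetGenerator, val_set: list[PairedSample],
             metric_config: MetricConfig | None = None) -> float:
    """Mean validation MS-SSIM between generator output and dense target."""
    generator.eval()
    dtype = generator.parameters()[0].data.dtype
    scores = []
    for s in val_set:
        out = generator(Tensor(s.x[None].astype(dtype))).data[0, 0]
        scores.append(ms_ssim(out, s.y[0], metric_config))
    generator.train()
    return float(np.mean(scores))


def fit(generator: UNetGenerator, discriminator: PatchDiscriminator | None,
        train_set: list[PairedSample], val_set: list[PairedSample],
        config: TrainConfig) -> TrainingRecord:
    """Alternating discriminator/generator optimization with MS-SSIM
    checkpointing.

    Fully seeded: a rerun with identically initialized networks and the same
    config reproduces the loss trajectory. Non-finite losses abort with a
    diagnostic record instead of raising.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    if config.adversarial and discriminator is None:
        raise ValueError(f"loss '{config.loss}' requires a discriminator")
    rng = np.random.default_rng(config.seed)
    dtype = np.dtype(config.dtype)
    generator.astype(dtype)
    if discriminator is not None:
        discriminator.astype(dtype)
    opt_g = Adam(generator.parameters(), lr=config.lr, betas=config.betas,
                 weight_decay=config.weight_decay)
    opt_d = (Adam(discriminator.parameters(), lr=config.lr, betas=config.betas,
                  weight_decay=config.weight_decay)
             if config.adversarial else None)
    record = TrainingRecord(loss_name=config.loss)
    generator.train()
    if discriminator is not None:
        discriminator.train()

    for epoch in range(config.epochs):
        order = rng.permutation(len(train_set))
        g_losses, d_losses = [], []
        for start in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[start:start + config.batch_size]]
            batch = [augment(s, config.crop, config.flip_prob, rng) for s in batch]
            x, y = _batch_tensors(batch, dtype)

            d_prob = None
            g_out = generator(x)
            if config.adversarial:
                # discriminator step on real vs generated (detached), then
                # the generator step against the updated discriminator
                ld = loss_discriminator(discriminator.mean_probability(y),
                                        discriminator.mean_probability(g_out.detach()))
                opt_d.zero_grad()
                ld.backward()
                opt_d.step()
                d_losses.append(ld.item())
                d_prob = discriminator.mean_probability(g_out)
            lg = _generator_loss(config, y, g_out, d_prob)
            opt_g.zero_grad()
            lg.backward()
            opt_g.step()
            g_losses.append(lg.item())
            if not np.isfinite(g_losses[-1]):
                record.aborted = True
                record.diagnostic = (f"non-finite generator loss at epoch {epoch}")
                logger.error(record.diagnostic)
                return record

        val = validate(generator, val_set, config.metric_config)
        record.epochs.append({
            "epoch": epoch,
            "loss": config.loss,
            "g_loss": float(np.mean(g_losses)),
            "d_loss": float(np.mean(d_losses)) if d_losses else None,
            "val_msssim": val,
        })
        if val > record.best_val_msssim:
            record.best_val_msssim = val
            record.best_epoch = epoch
            record.best_state = [p.copy() for p in generator.state_arrays()]
    return record


def transfer_finetune(pretrained: UNetGenerator, spec_expected: GeneratorSpec,
                      train_set: list[PairedSample], val_set: list[PairedSample],
                      config: TrainConfig,
                      discriminator_seed: int = 0) -> tuple[UNetGenerator, TrainingRecord]:
    """Fine-tune a pre-trained 2D generator on PACT-style pairs.

    Switches from the pre-training loss to the full adversarial 2D loss with
    a freshly initialized discriminator. Raises if the pre-trained generator's
    architecture differs from `spec_expected` (differing fields are listed).
    """
    actual = pretrained.spec
    diffs = [f for f in actual.to_dict()
             if actual.to_dict()[f] != spec_expected.to_dict()[f]]
    if diffs:
        raise ValueError(f"generator spec mismatch in fields: {diffs}")
    config = replace(config, loss="2d_adversarial")
    disc = build_discriminator(
        DiscriminatorSpec(dim=actual.dim, base_width=max(actual.base_width // 2, 4)),
        seed=discriminator_seed)
    record = fit(pretrained, disc, train_set, val_set, config)
    return pretrained, record
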