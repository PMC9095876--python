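"""Training losses (closed forms), augmentation and the fit loop."""

import numpy as np
import pytest

from palocal.grad import Tensor
from palocal.metrics import MetricConfig, ms_ssim
from palocal.networks import (DiscriminatorSpec, GeneratorSpec,
                              build_discriminator, build_generator)
from palocal.training import (PairedSample, TrainConfig, augment, fit,
                              loss_discriminator, loss_generator_2d,
                              loss_generator_3d, loss_pretrain_2d,
                              ms_ssim_tensor, transfer_finetune, validate)

LOG2 = float(np.log(2.0))  # 0.6931...


def _pair(rng, size=16):
    from scipy.ndimage import gaussian_filter

    y = gaussian_filter(rng.random((size, size)), 1.5)
    y = (y - y.min()) / (y.max() - y.min())
    x = np.clip(y * rng.random((size, size)), 0.0, 1.0)
    return PairedSample(x[None], y[None])


# ---------------------------------------------------------------------------
# closed-form loss values
# ---------------------------------------------------------------------------

def test_loss_3d_closed_form(random_image):
    # perfect generator output, undecided discriminator: -log 0.5 = log 2
    val = loss_generator_3d(random_image, random_image, 0.5)
    assert val.item() == pytest.approx(LOG2, abs=1e-12)
    # MAE term scales with coefficient 0.01 exactly
    off = np.clip(random_image + 0.1, 0, 1)
    mae = float(np.mean(np.abs(random_image - off)))
    val = loss_generator_3d(random_image, off, 0.5)
    assert val.item() == pytest.approx(0.01 * mae + LOG2, abs=1e-12)


def test_loss_pretrain_2d_zero_at_perfect_output(random_image):
    val = loss_pretrain_2d(random_image, random_image)
    assert val.item() == pytest.approx(0.0, abs=1e-9)


def test_loss_2d_adversarial_closed_form(random_image):
    # perfect output: MAE = 0, MS-SSIM = 1, so only -log D(G(x)) remains
    val = loss_generator_2d(random_image, random_image, 0.5)
    assert val.item() == pytest.approx(LOG2, abs=1e-9)


def test_loss_coefficients_exact(random_image, rng):
    degraded = np.clip(random_image + rng.normal(0, 0.1, random_image.shape), 0, 1)
    mae = float(np.mean(np.abs(random_image - degraded)))
    mss = ms_ssim(random_image, degraded)
    pre = loss_pretrain_2d(random_image, degraded).item()
    assert pre == pytest.approx(0.3 * mae + 0.7 * (1.0 - mss), abs=1e-6)
    adv = loss_generator_2d(random_image, degraded, 0.5).item()
    assert adv == pytest.approx(0.03 * mae + 0.07 * (1.0 - mss) + LOG2, abs=1e-6)


def test_loss_discriminator_closed_forms():
    assert loss_discriminator(0.5, 0.5).item() == pytest.approx(2 * LOG2, abs=1e-12)
    # perfect discriminator -> loss approaches 0
    assert loss_discriminator(1.0 - 1e-7, 1e-7).item() == pytest.approx(0.0, abs=1e-5)
    with pytest.raises(ValueError, match="probability"):
        loss_discriminator(1.5, 0.5)


def test_msssim_tensor_matches_numpy_metric(random_image, rng):
    other = np.clip(random_image + rng.normal(0, 0.1, random_image.shape), 0, 1)
    t = ms_ssim_tensor(Tensor(random_image[None, None]),
                       Tensor(other[None, None]))
    assert t.item() == pytest.approx(ms_ssim(random_image, other), abs=1e-6)


def test_msssim_tensor_gradient_direction(rng):
    """Gradient ascent on MS-SSIM moves the image toward the target."""
    from scipy.ndimage import gaussian_filter

    target = gaussian_filter(rng.random((32, 32)), 2.0)
    target = (target - target.min()) / (target.max() - target.min())
    img = Tensor(np.full((1, 1, 32, 32), 0.5), requires_grad=True)
    before = ms_ssim_tensor(img, Tensor(target[None, None])).item()
    for _ in range(30):
        score = ms_ssim_tensor(img, Tensor(target[None, None]))
        img.zero_grad()
        score.backward()
        img.data += 0.5 * img.grad
    after = ms_ssim_tensor(img, Tensor(target[None, None])).item()
    assert after > before + 0.05


# ---------------------------------------------------------------------------
# samples and augmentation
# ---------------------------------------------------------------------------

def test_paired_sample_validation():
    with pytest.raises(ValueError, match="aligned"):
        PairedSample(np.zeros((1, 8, 8)), np.zeros((1, 8, 9)))
    with pytest.raises(ValueError, match="normalized"):
        PairedSample(np.full((1, 8, 8), 2.0), np.zeros((1, 8, 8)))


def test_augment_keeps_pairs_aligned(rng):
    x = rng.random((2, 12, 12, 8))
    y = rng.random((1, 12, 12, 8))
    # encode position in both so any misalignment is visible
    sample = PairedSample(x, y)
    out = augment(sample, crop=(8, 8, 8), flip_prob=1.0, rng=rng)
    assert out.x.shape == (2, 8, 8, 8)
    assert out.y.shape == (1, 8, 8, 8)
    # the same crop+flip applied to y: find it by exhaustive search over origins
    found = False
    for ox in range(5):
        for oy in range(5):
            for oz in range(1):
                ref = y[:, ox:ox + 8, oy:oy + 8, 0:8][:, ::-1, ::-1, :]
                if np.array_equal(ref, out.y):
                    # x must come from the SAME origin and flips
                    refx = x[:, ox:ox + 8, oy:oy + 8, 0:8][:, ::-1, ::-1, :]
                    assert np.array_equal(refx, out.x)
                    found = True
    assert found


def test_augment_never_flips_axial_axis(rng):
    x = np.linspace(0, 1, 8)[None, None, None, :] * np.ones((1, 4, 4, 8))
    sample = PairedSample(x, x.copy())
    for _ in range(10):
        out = augment(sample, crop=None, flip_prob=1.0, rng=rng)
        assert np.array_equal(out.x[0, 0, 0, :], x[0, 0, 0, :])  # axial intact


def test_augment_crop_validation(rng):
    s = PairedSample(np.zeros((1, 8, 8)), np.zeros((1, 8, 8)))
    with pytest.raises(ValueError, match="larger"):
        augment(s, crop=(9, 9), flip_prob=0.0, rng=rng)
    with pytest.raises(ValueError, match="rank"):
        augment(s, crop=(4,), flip_prob=0.0, rng=rng)


def test_augment_crop_origin_covers_volume(rng):
    """150x150x64 volumes crop to 64^3 anywhere in the lateral plane."""
    x = np.zeros((1, 150, 150, 64))
    s = PairedSample(x, x.copy())
    out = augment(s, crop=(64, 64, 64), flip_prob=0.0, rng=rng)
    assert out.x.shape == (1, 64, 64, 64)


# ---------------------------------------------------------------------------
# fit loop
# ---------------------------------------------------------------------------

def _tiny_setup(rng, n=6, adversarial=False):
    spec = GeneratorSpec(dim=2, in_channels=1, base_width=4, levels=1,
                         upsample="pixel_shuffle", batchnorm=False)
    gen = build_generator(spec, seed=0)
    disc = (build_discriminator(DiscriminatorSpec(dim=2, base_width=4), seed=0)
            if adversarial else None)
    samples = [_pair(rng) for _ in range(n)]
    return gen, disc, samples[:-2], samples[-2:]


def test_fit_bookkeeping_and_checkpointing(rng):
    gen, _, train_set, val_set = _tiny_setup(rng)
    cfg = TrainConfig(epochs=3, loss="2d_pretrain", batch_size=2, seed=0,
                      metric_config=MetricConfig())
    rec = fit(gen, None, train_set, val_set, cfg)
    assert len(rec.epochs) == 3
    assert rec.loss_name == "2d_pretrain"
    vals = [e["val_msssim"] for e in rec.epochs]
    assert rec.best_val_msssim == pytest.approx(max(vals))
    assert rec.best_epoch == int(np.argmax(vals))
    assert rec.best_state is not None
    assert all(e["d_loss"] is None for e in rec.epochs)
    # restoring the best state reproduces the best validation score
    gen.load_state_arrays(rec.best_state)
    assert validate(gen, val_set) == pytest.approx(rec.best_val_msssim, abs=1e-6)


def test_fit_deterministic_under_seed(rng):
    losses = []
    for _ in range(2):
        gen, _, train_set, val_set = _tiny_setup(rng_copy := np.random.default_rng(5))
        cfg = TrainConfig(epochs=2, loss="2d_pretrain", batch_size=2, seed=3)
        rec = fit(gen, None, train_set, val_set, cfg)
        losses.append([e["g_loss"] for e in rec.epochs])
    assert losses[0] == losses[1]


def test_fit_adversarial_records_discriminator_loss(rng):
    gen, disc, train_set, val_set = _tiny_setup(rng, adversarial=True)
    cfg = TrainConfig(epochs=2, loss="2d_adversarial", batch_size=2, seed=0)
    rec = fit(gen, disc, train_set, val_set, cfg)
    assert all(np.isfinite(e["d_loss"]) for e in rec.epochs)
    assert all(np.isfinite(e["g_loss"]) for e in rec.epochs)


def test_fit_requires_discriminator_for_adversarial(rng):
    gen, _, train_set, val_set = _tiny_setup(rng)
    cfg = TrainConfig(epochs=1, loss="2d_adversarial")
    with pytest.raises(ValueError, match="discriminator"):
        fit(gen, None, train_set, val_set, cfg)


def test_transfer_finetune_switches_loss_and_checks_spec(rng):
    gen, _, train_set, val_set = _tiny_setup(rng)
    cfg = TrainConfig(epochs=1, loss="2d_pretrain", batch_size=2, seed=0)
    tuned, rec = fit_then_transfer(gen, train_set, val_set, cfg)
    assert rec.loss_name == "2d_adversarial"
    assert tuned is gen
    # spec mismatch is rejected with the differing fields named
    other_spec = GeneratorSpec(dim=2, in_channels=1, base_width=8, levels=1,
                               upsample="pixel_shuffle", batchnorm=False)
    with pytest.raises(ValueError, match="base_width"):
        transfer_finetune(gen, other_spec, train_set, val_set, cfg)


def fit_then_transfer(gen, train_set, val_set, cfg):
    return transfer_finetune(gen, gen.spec, train_set, val_set, cfg)


def test_transfer_finetune_zero_epochs_is_identity(rng):
    gen, _, train_set, val_set = _tiny_setup(rng)
    before = [a.copy() for a in gen.state_arrays()]
    cfg = TrainConfig(epochs=0, loss="2d_pretrain", batch_size=2, seed=0)
    tuned, rec = transfer_finetune(gen, gen.spec, train_set, val_set, cfg)
    assert rec.epochs == []
    assert all(np.array_equal(a, b.astype(a.dtype))
               for a, b in zip(tuned.state_arrays(), before))


def test_train_config_validation():
    with pytest.raises(ValueError, match="unknown loss"):
        TrainConfig(loss="nope")
    with pytest.raises(ValueError):
        TrainConfig(epochs=-1)
    with pytest.raises(ValueError):
        TrainConfig(flip_prob=1.5)
    assert TrainConfig(loss="3d").adversarial
    assert not TrainConfig(loss="2d_pretrain").adversarial
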