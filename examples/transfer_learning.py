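"""Does pre-training help? Paired-seed comparison (expensive: ~30 min CPU).

For each seed, fine-tunes (a) a generator pre-trained with the structural
loss and (b) a freshly initialized generator, adversarially on a second
synthetic dataset, and compares their best validation MS-SSIM. This is the
transfer-learning question at desk scale: the 2D network is normally
pre-trained on one angiographic domain before fine-tuning on the (smaller)
target domain.

This script is a standalone narrative study: ten full training runs take far
longer than the bundled test suite, so it is not part of it.
"""

import logging
from dataclasses import replace

import numpy as np

from palocal.io_preprocess import generate_paired_samples
from palocal.networks import GeneratorSpec, build_generator
from palocal.training import TrainConfig, fit, transfer_finetune

logging.basicConfig(level=logging.WARNING)

SPEC = GeneratorSpec(dim=2, in_channels=1, base_width=8, levels=2,
                     upsample="pixel_shuffle", batchnorm=False)
N_SEEDS = 5
wins = 0

for seed in range(N_SEEDS):
    rng = np.random.default_rng(seed)
    s_pre, s_fin, s_init = (int(v) for v in rng.integers(0, 2**31 - 1, 3))

    source = generate_paired_samples(40, seed=s_pre)      # pre-training domain
    target = generate_paired_samples(24, seed=s_fin)      # fine-tuning domain
    tr_s, va_s = source[:36], source[36:]
    tr_t, va_t = target[:20], target[20:]

    cfg = TrainConfig(epochs=20, loss="2d_pretrain", batch_size=2, seed=s_fin)

    # (a) pre-train on the source domain, then fine-tune adversarially
    pretrained = build_generator(SPEC, seed=s_init)
    fit(pretrained, None, tr_s, va_s, cfg)
    _, rec_transfer = transfer_finetune(pretrained, SPEC, tr_t, va_t,
                                        replace(cfg, epochs=10),
                                        discriminator_seed=s_init)

    # (b) same architecture and schedule length, no pre-training
    scratch = build_generator(SPEC, seed=s_init)
    _, rec_scratch = transfer_finetune(scratch, SPEC, tr_t, va_t,
                                       replace(cfg, epochs=10),
                                       discriminator_seed=s_init)

    better = rec_transfer.best_val_msssim > rec_scratch.best_val_msssim
    wins += int(better)
    print(f"seed {seed}: pretrained {rec_transfer.best_val_msssim:.4f} vs "
          f"scratch {rec_scratch.best_val_msssim:.4f} -> "
          f"{'pretraining wins' if better else 'scratch wins'}")

print(f"\npre-training better on {wins}/{N_SEEDS} seeds")
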