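"""Image-quality metrics: identities, closed forms and degradation curves."""

import numpy as np
from scipy.ndimage import gaussian_filter

from palocal.metrics import MetricConfig, ms_ssim, psnr, ssim

rng = np.random.default_rng(0)
img = gaussian_filter(rng.random((128, 128)), 2.0)
img = (img - img.min()) / (img.max() - img.min())

print(f"ms_ssim(a, a)            = {ms_ssim(img, img):.6f}")
print(f"psnr at MSE 0.01         = "
      f"{psnr(np.zeros((10, 10)), np.full((10, 10), 0.1)):.6f} dB")

noisy = np.clip(img + rng.normal(0, 0.1, img.shape), 0, 1)
single = MetricConfig(scales=1, weights=(1.0,))
print(f"single-scale MS-SSIM     = {ms_ssim(img, noisy, single):.6f}")
print(f"SSIM                     = {ssim(img, noisy):.6f}  (identical)")

print("\nnoise sigma  PSNR (dB)  MS-SSIM")
noise = rng.normal(0, 1.0, img.shape)
for s in (0.02, 0.05, 0.1, 0.2, 0.4):
    deg = np.clip(img + s * noise, 0, 1)
    print(f"{s:10.2f}  {psnr(img, deg):9.2f}  {ms_ssim(img, deg):.4f}")

# 3D volumes use the same functions
vol = gaussian_filter(rng.random((32, 32, 32)), 2.0)
vol = (vol - vol.min()) / (vol.max() - vol.min())
noisy_vol = np.clip(vol + rng.normal(0, 0.1, vol.shape), 0, 1)
print(f"\n3D MS-SSIM               = {ms_ssim(vol, noisy_vol):.4f}")
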