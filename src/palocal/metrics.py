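"""Dimension-agnostic image-quality metrics: PSNR, SSIM and MS-SSIM.

Works on 2D planar images and 3D volumes alike. SSIM follows the standard
local-statistics construction with a Gaussian weighting window and stability
constants C1 = (k1 R)^2, C2 = (k2 R)^2 for dynamic range R; MS-SSIM is the
usual dyadic multiscale aggregation, combining contrast/structure terms from
every scale with the luminance term at the coarsest scale, each raised to its
scale weight.

These metrics serve both evaluation (comparing network output and sparse
input against the dense localization ground truth) and the structural term of
the 2D training losses (via the differentiable twin in
:mod:`palocal.training`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

logger = logging.getLogger(__name__)

#: Standard five-scale MS-SSIM weights (coarse-to-fine aggregation exponents).
DEFAULT_MSSSIM_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

__all__ = ["MetricConfig", "psnr", "ssim", "ms_ssim", "DEFAULT_MSSSIM_WEIGHTS",
           "gaussian_window_1d", "max_feasible_scales"]


@dataclass(frozen=True)
class MetricConfig:
    """Shared configuration for PSNR / SSIM / MS-SSIM.

    Parameters
    ----------
    data_range : peak signal value (1.0 for normalized amplitude images).
    k1, k2 : SSIM stability constants, C1 = (k1 R)^2 and C2 = (k2 R)^2.
    win_size : Gaussian window length in pixels (odd); clipped per axis on
        small inputs.
    win_sigma : Gaussian window standard deviation in pixels.
    scales : number of dyadic scales for MS-SSIM. ``None`` auto-clamps to the
        largest feasible count (at most 5) for the given input size.
    weights : per-scale exponents; normalized to sum to 1.
    """

    data_range: float = 1.0
    k1: float = 0.01
    k2: float = 0.03
    win_size: int = 11
    win_sigma: float = 1.5
    scales: int | None = None
    weights: tuple[float, ...] = field(default=DEFAULT_MSSSIM_WEIGHTS)

    def __post_init__(self):
        if self.data_range <= 0:
            raise ValueError("data_range must be positive")
        if self.win_size < 1 or self.win_size % 2 == 0:
            raise ValueError("win_size must be odd and positive")
        if any(w < 0 for w in self.weights):
            raise ValueError("scale weights must be non-negative")
        total = float(sum(self.weights))
        if total <= 0:
            raise ValueError("scale weights must not all be zero")
        object.__setattr__(self, "weights", tuple(w / total for w in self.weights))

    @property
    def c1(self) -> float:
        return (self.k1 * self.data_range) ** 2

    @property
    def c2(self) -> float:
        return (self.k2 * self.data_range) ** 2


def gaussian_window_1d(size: int, sigma: float) -> np.ndarray:
    """Normalized 1-D Gaussian window of odd length `size`."""
    r = np.arange(size) - (size - 1) / 2
    w = np.exp(-(r**2) / (2 * sigma**2))
    return w / w.sum()


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def _squeeze_singletons(a: np.ndarray, b: np.ndarray):
    """Drop size-1 axes so 3D metrics reduce exactly to 2D on flat volumes."""
    keep = tuple(i for i, n in enumerate(a.shape) if n > 1)
    if len(keep) == a.ndim:
        return a, b
    if not keep:  # degenerate single-pixel image
        return a.reshape(1), b.reshape(1)
    return a.squeeze(), b.squeeze()


def psnr(a: np.ndarray, b: np.ndarray, config: MetricConfig | None = None) -> float:
    """Peak signal-to-noise ratio, 10 log10(R^2 / MSE), in decibels.

    Identical inputs (zero MSE) return +inf with a logged notice.
    """
    config = config or MetricConfig()
    a, b = _check_pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        logger.info("psnr: identical inputs, returning +inf sentinel")
        return float("inf")
    return float(10.0 * np.log10(config.data_range**2 / mse))


def _local_mean(x: np.ndarray, windows: list[np.ndarray]) -> np.ndarray:
    """Separable Gaussian filtering, then crop to the valid interior."""
    y = x
    for ax, w in enumerate(windows):
        if len(w) > 1:
            y = correlate1d(y, w, axis=ax, mode="constant")
    sl = tuple(slice((len(w) - 1) // 2, n - (len(w) - 1) // 2)
               for w, n in zip(windows, x.shape))
    return y[sl]


def _axis_windows(shape: tuple[int, ...], config: MetricConfig) -> list[np.ndarray]:
    wins = []
    for n in shape:
        size = min(config.win_size, n if n % 2 == 1 else n - 1)
        wins.append(gaussian_window_1d(size, config.win_sigma))
    return wins


def _ssim_components(a: np.ndarray, b: np.ndarray, config: MetricConfig):
    """Mean SSIM and mean contrast-structure term over the valid interior."""
    wins = _axis_windows(a.shape, config)
    mu_a = _local_mean(a, wins)
    mu_b = _local_mean(b, wins)
    var_a = _local_mean(a * a, wins) - mu_a**2
    var_b = _local_mean(b * b, wins) - mu_b**2
    cov = _local_mean(a * b, wins) - mu_a * mu_b
    c1, c2 = config.c1, config.c2
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * cov + c2) / (var_a + var_b + c2)
    return float(np.mean(lum * cs)), float(np.mean(cs))


def ssim(a: np.ndarray, b: np.ndarray, config: MetricConfig | None = None) -> float:
    """Mean structural similarity with Gaussian local weighting."""
    config = config or MetricConfig()
    a, b = _check_pair(a, b)
    a, b = _squeeze_singletons(a, b)
    if min(a.shape) < 2 and a.size > 1:
        raise ValueError("image too small for SSIM")
    if config.win_size > max(a.shape):
        raise ValueError(
            f"window size {config.win_size} exceeds every image axis {a.shape}")
    return _ssim_components(a, b, config)[0]


def max_feasible_scales(shape: tuple[int, ...], config: MetricConfig) -> int:
    """Largest scale count whose coarsest dyadic level still fits the window."""
    s = 0
    n = min(shape)
    while n >= config.win_size:
        s += 1
        n //= 2
    return s


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2x average pooling on every axis (trailing remainder cropped)."""
    sl = tuple(slice(0, (n // 2) * 2) for n in x.shape)
    y = x[sl]
    for ax in range(y.ndim):
        shape = y.shape[:ax] + (y.shape[ax] // 2, 2) + y.shape[ax + 1:]
        y = y.reshape(shape).mean(axis=ax + 1)
    return y


def ms_ssim(a: np.ndarray, b: np.ndarray, config: MetricConfig | None = None) -> float:
    """Multiscale SSIM over a dyadic pyramid.

    Contrast/structure terms from every scale and the luminance term at the
    coarsest scale are each raised to their normalized scale weight and
    multiplied. Negative contrast-structure means are clamped at zero, so the
    score lies in [0, 1] (and in (0, 1] for non-negative inputs).
    """
    config = config or MetricConfig()
    a, b = _check_pair(a, b)
    a, b = _squeeze_singletons(a, b)
    feasible = max_feasible_scales(a.shape, config)
    if feasible < 1:
        raise ValueError(
            f"window size {config.win_size} does not fit image of shape {a.shape}")
    if config.scales is None:
        n_scales = min(5, feasible)
        if n_scales < 5:
            logger.info("ms_ssim: auto-clamped scale count to %d for shape %s",
                        n_scales, a.shape)
    else:
        if config.scales < 1:
            raise ValueError("scale count must be >= 1")
        if config.scales > feasible:
            raise ValueError(
                f"requested {config.scales} scales infeasible for shape {a.shape}; "
                f"maximum feasible scale count is {feasible}")
        n_scales = config.scales
    weights = np.asarray(config.weights[:n_scales], dtype=float)
    weights = weights / weights.sum()
    score = 1.0
    for j in range(n_scales):
        s, cs = _ssim_components(a, b, config)
        term = s if j == n_scales - 1 else cs
        score *= max(term, 0.0) ** weights[j]
        if j < n_scales - 1:
            a, b = _downsample2(a), _downsample2(b)
    return float(score)
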