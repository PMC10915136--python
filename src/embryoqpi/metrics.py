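"""Image-similarity metrics and the combination training loss.

PSNR, multi-scale structural similarity (MS-SSIM) and a squared Pearson
loss, plus their weighted combination

    L = ε₁·L1 + ε₂·(1 − MS-SSIM) + ε₃·(1 − r)²,   (ε₁, ε₂, ε₃) = (2, 1, 0.5)

used to evaluate a nucleus-channel predictor against its target.  MS-SSIM
follows the standard construction: a Gaussian window (11 px, σ = 1.5),
luminance/contrast/structure comparisons with the published exponents
(0.0448, 0.2856, 0.3001, 0.2363, 0.1333 over 5 dyadic scales),
contrast·structure averaged per scale for scales below the top and the
full l·c·s product at the top scale — so with one scale the value reduces
exactly to single-scale SSIM.  Negative per-scale means are combined with
sign-preserving powers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

#: published per-scale exponents (α_M = β_j = γ_j at each scale)
STANDARD_WEIGHTS = (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)


@dataclass
class MetricConfig:
    msssim_scales: int = 5
    scale_weights: tuple = STANDARD_WEIGHTS
    window_size: int = 11
    gaussian_sigma: float = 1.5
    k1: float = 0.01
    k2: float = 0.03
    data_range: float = 1.0
    loss_weights: tuple[float, float, float] = (2.0, 1.0, 0.5)

    def __post_init__(self):
        if self.msssim_scales < 1:
            raise ValueError("need at least one scale")
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be nonnegative")


def _check_pair(y, y_hat):
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def psnr(y, y_hat, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; identical images give ``inf``."""
    y, y_hat = _check_pair(y, y_hat)
    mse = float(np.mean((y - y_hat) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(data_range**2 / mse)


def _ssim_components(y, y_hat, config: MetricConfig):
    """Per-pixel luminance and contrast·structure maps (Gaussian window)."""
    sigma = config.gaussian_sigma
    trunc = ((config.window_size - 1) / 2) / sigma  # 11-px window
    blur = lambda a: ndi.gaussian_filter(a, sigma, truncate=trunc, mode="reflect")
    c1 = (config.k1 * config.data_range) ** 2
    c2 = (config.k2 * config.data_range) ** 2

    mu_x, mu_y = blur(y), blur(y_hat)
    sxx = blur(y * y) - mu_x * mu_x
    syy = blur(y_hat * y_hat) - mu_y * mu_y
    sxy = blur(y * y_hat) - mu_x * mu_y
    luminance = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    cs = (2 * sxy + c2) / (sxx + syy + c2)  # contrast·structure (C3 = C2/2)
    return luminance, cs


def _downsample(a):
    """2× average pooling (pad-reflect to even size first)."""
    if a.shape[0] % 2:
        a = np.concatenate([a, a[-1:]], axis=0)
    if a.shape[1] % 2:
        a = np.concatenate([a, a[:, -1:]], axis=1)
    return 0.25 * (a[::2, ::2] + a[1::2, ::2] + a[::2, 1::2] + a[1::2, 1::2])


def _signed_power(v: float, w: float) -> float:
    return float(np.sign(v) * np.abs(v) ** w)


def ms_ssim(y, y_hat, config: MetricConfig = MetricConfig()) -> float:
    """Multi-scale structural similarity in [−1, 1].

    If the images are too small for the requested number of dyadic scales
    the scale count is reduced with a warning (the last configured weights
    are dropped and the remainder renormalized).
    """
    y, y_hat = _check_pair(y, y_hat)
    scales = config.msssim_scales
    min_size = config.window_size * 2 ** (scales - 1)
    if min(y.shape) < min_size:
        scales = max(1, int(np.floor(np.log2(min(y.shape) / config.window_size))) + 1)
        warnings.warn(
            f"images of shape {y.shape} support only {scales} MS-SSIM scale(s); "
            f"reducing from {config.msssim_scales}"
        )
    # exponents truncated to the scale count and normalized to sum 1, so a
    # single-scale configuration reduces exactly to plain SSIM
    weights = np.asarray(config.scale_weights[:scales], dtype=float)
    weights = weights / weights.sum()

    pad = (config.window_size - 1) // 2  # filter-edge crop, as is standard
    value = 1.0
    a, b = y, y_hat
    for j in range(scales):
        luminance, cs = _ssim_components(a, b, config)
        view = (slice(pad, -pad or None),) * cs.ndim if min(cs.shape) > 2 * pad else ()
        if j < scales - 1:
            value *= _signed_power(float(cs[view].mean()), weights[j])
            a, b = _downsample(a), _downsample(b)
        else:
            value *= _signed_power(float((luminance * cs)[view].mean()), weights[j])
    return float(value)


def ms_ssim_loss(y, y_hat, config: MetricConfig = MetricConfig()) -> float:
    """Loss form: 1 − MS-SSIM."""
    return 1.0 - ms_ssim(y, y_hat, config)


def pearson_loss(y, y_hat) -> float:
    """Squared complement of the Pearson correlation: (1 − r)² ∈ [0, 4]."""
    y, y_hat = _check_pair(y, y_hat)
    yc = y - y.mean()
    hc = y_hat - y_hat.mean()
    denom = np.sqrt((yc**2).sum() * (hc**2).sum())
    if denom == 0.0:
        raise ValueError("Pearson correlation undefined for a constant image")
    r = float((yc * hc).sum() / denom)
    return (1.0 - r) ** 2


def l1_loss(y, y_hat) -> float:
    """Mean absolute error."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.abs(y - y_hat).mean())


def combo_loss(y, y_hat, config: MetricConfig = MetricConfig()) -> float:
    """ε₁·L1 + ε₂·(1 − MS-SSIM) + ε₃·(1 − r)² with defaults (2, 1, 0.5)."""
    e1, e2, e3 = config.loss_weights
    total = 0.0
    if e1:
        total += e1 * l1_loss(y, y_hat)
    if e2:
        total += e2 * ms_ssim_loss(y, y_hat, config)
    if e3:
        total += e3 * pearson_loss(y, y_hat)
    return total
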