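"""Full-reference image quality metrics: MSE, PSNR, SSIM.

PSNR is ``10 log10(L^2 / MSE)`` in dB with ``L`` the dynamic range; identical
images yield the ``+inf`` sentinel.  SSIM is offered in two modes: ``global``
evaluates the single-window formula once over the whole image, ``windowed``
averages it over 11x11 Gaussian-weighted (sigma 1.5) sliding windows.
Stabilizers are ``C1 = (K1 L)^2`` and ``C2 = (K2 L)^2`` with the customary
K1 = 0.01, K2 = 0.03.

Reported metrics are conventionally computed on the 8-bit 0-255 scale; use
:func:`report` to rescale :class:`~lpwave.wavelets.ImageGrid` inputs by their
declared dynamic range first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, InputError
from .wavelets import ImageGrid

SSIMMode = Literal["global", "windowed"]

__all__ = ["MetricsReport", "mse", "psnr", "ssim", "report"]


@dataclass(frozen=True)
class MetricsReport:
    mse: float
    psnr_db: float
    ssim: float
    L: float
    ssim_mode: SSIMMode


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise InputError("empty image")
    return x, y


def mse(x, y) -> float:
    """Mean squared difference in the images' native intensity scale."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x, y, L: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(L^2 / MSE)`` in dB."""
    if not L > 0:
        raise ConfigurationError(f"dynamic range L must be > 0, got {L}")
    err = mse(x, y)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(L * L / err)


def _ssim_terms(mu_x, mu_y, var_x, var_y, cov_xy, C1: float, C2: float):
    num = (2.0 * mu_x * mu_y + C1) * (2.0 * cov_xy + C2)
    den = (mu_x ** 2 + mu_y ** 2 + C1) * (var_x + var_y + C2)
    return num / den


def ssim(
    x,
    y,
    L: float = 255.0,
    mode: SSIMMode = "global",
    K1: float = 0.01,
    K2: float = 0.03,
) -> float:
    """Structural similarity between `x` and `y`.

    ``global`` mode evaluates means/variances/covariance once over the full
    image; ``windowed`` mode averages the same expression over Gaussian
    sliding windows (11 taps, sigma 1.5).
    """
    if not L > 0:
        raise ConfigurationError(f"dynamic range L must be > 0, got {L}")
    if mode not in ("global", "windowed"):
        raise ConfigurationError(f"unknown ssim mode {mode!r}")
    x, y = _check_pair(x, y)
    C1 = (K1 * L) ** 2
    C2 = (K2 * L) ** 2
    if mode == "global":
        mu_x = float(np.mean(x))
        mu_y = float(np.mean(y))
        var_x = float(np.mean((x - mu_x) ** 2))
        var_y = float(np.mean((y - mu_y) ** 2))
        cov = float(np.mean((x - mu_x) * (y - mu_y)))
        return float(_ssim_terms(mu_x, mu_y, var_x, var_y, cov, C1, C2))
    # windowed: Gaussian-weighted local statistics, truncated to 11x11
    sigma = 1.5
    truncate = 3.5  # radius 5 -> 11 taps
    blur = lambda a: gaussian_filter(a, sigma=sigma, truncate=truncate, mode="reflect")
    mu_x = blur(x)
    mu_y = blur(y)
    var_x = blur(x * x) - mu_x ** 2
    var_y = blur(y * y) - mu_y ** 2
    cov = blur(x * y) - mu_x * mu_y
    return float(np.mean(_ssim_terms(mu_x, mu_y, var_x, var_y, cov, C1, C2)))


def report(
    x: ImageGrid,
    y: ImageGrid,
    ssim_mode: SSIMMode = "global",
    K1: float = 0.01,
    K2: float = 0.03,
) -> MetricsReport:
    """Metrics on the 8-bit scale: both grids are rescaled to 0-255 by their
    declared dynamic ranges before evaluation."""
    xs = x.pixels * (255.0 / x.dynamic_range)
    ys = y.pixels * (255.0 / y.dynamic_range)
    return MetricsReport(
        mse=mse(xs, ys),
        psnr_db=psnr(xs, ys, 255.0),
        ssim=ssim(xs, ys, 255.0, ssim_mode, K1, K2),
        L=255.0,
        ssim_mode=ssim_mode,
    )
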