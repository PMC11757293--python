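"""Synthetic brain-like phantoms and Gaussian noise injection.

The phantom is a piecewise-smooth composition of ellipses — a bright
skull-like ring, darker brain tissue, dark ventricle-like lobes and a set of
seeded nested elliptical structures — plus a low-amplitude smooth texture
field.  It exhibits both sharp edges and smooth regions on a normalized
[0, 1] intensity scale and is bit-reproducible for a fixed seed.

Noise is additive i.i.d. zero-mean Gaussian parameterized by its *variance*
on the normalized scale (0.01-0.05 in the benchmark protocol).  Output is
deliberately not clipped by default: clipping would bias downstream noise
and slope estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .wavelets import ImageGrid

__all__ = ["PhantomSpec", "NoiseSpec", "make_brain_phantom", "add_gaussian_noise"]


@dataclass(frozen=True)
class PhantomSpec:
    size: int = 256
    n_structures: int = 8
    contrast_range: tuple[float, float] = (0.15, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ConfigurationError(f"phantom size must be >= 32, got {self.size}")
        lo, hi = self.contrast_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"contrast_range must be ordered within [0, 1], got {self.contrast_range}")


@dataclass(frozen=True)
class NoiseSpec:
    variance: float
    seed: int = 0
    distribution: str = "gaussian-additive"

    def __post_init__(self) -> None:
        if not (0.0 < self.variance <= 1.0):
            raise ConfigurationError(f"variance must be in (0, 1], got {self.variance}")
        if self.distribution != "gaussian-additive":
            raise ConfigurationError(f"unsupported distribution {self.distribution!r}")


def _ellipse_mask(yy: np.ndarray, xx: np.ndarray, cx: float, cy: float,
                  a: float, b: float, angle: float = 0.0) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    xr = (xx - cx) * c + (yy - cy) * s
    yr = -(xx - cx) * s + (yy - cy) * c
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def make_brain_phantom(spec: PhantomSpec = PhantomSpec()) -> ImageGrid:
    """Deterministic brain-like phantom on the [0, 1] scale."""
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    coords = np.linspace(-1.0, 1.0, n)
    xx, yy = np.meshgrid(coords, coords)

    img = np.full((n, n), 0.02)
    # skull ring: bright outer ellipse with darker interior
    img[_ellipse_mask(yy, xx, 0.0, 0.0, 0.92, 0.88)] = 0.95
    img[_ellipse_mask(yy, xx, 0.0, 0.0, 0.84, 0.80)] = 0.08   # CSF gap
    brain = _ellipse_mask(yy, xx, 0.0, 0.0, 0.78, 0.74)
    img[brain] = 0.45

    lo, hi = spec.contrast_range
    for _ in range(spec.n_structures):
        cx, cy = rng.uniform(-0.45, 0.45, size=2)
        a = rng.uniform(0.06, 0.30)
        b = rng.uniform(0.06, 0.30)
        ang = rng.uniform(0.0, np.pi)
        level = rng.uniform(lo, hi)
        mask = _ellipse_mask(yy, xx, cx, cy, a, b, ang) & brain
        img[mask] = level

    # ventricle-like dark lobes near the center
    for sx in (-1.0, 1.0):
        mask = _ellipse_mask(yy, xx, sx * 0.14, -0.05, 0.10, 0.26, sx * 0.35) & brain
        img[mask] = 0.12

    # smooth low-amplitude texture confined to the brain tissue
    texture = gaussian_filter(rng.normal(size=(n, n)), sigma=n / 32.0)
    peak = np.max(np.abs(texture))
    if peak > 0:
        img = img + np.where(brain, 0.04 * texture / peak, 0.0)

    return ImageGrid(np.clip(img, 0.0, 1.0), dynamic_range=1.0)


def add_gaussian_noise(image: ImageGrid, spec: NoiseSpec, clip: bool = False) -> ImageGrid:
    """Additive zero-mean white Gaussian noise with the requested variance.

    Unclipped by default; pass ``clip=True`` to clamp the result to
    ``[0, dynamic_range]``.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(spec.variance), size=image.pixels.shape)
    noisy = image.pixels + noise
    if clip:
        noisy = np.clip(noisy, 0.0, image.dynamic_range)
    return ImageGrid(noisy, dynamic_range=image.dynamic_range)
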