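"""Linear prediction factor relating a reference image to a noisy image.

``beta`` is the least-squares slope through the origin that minimizes the
mean squared prediction error ``mean((noisy - beta * reference)^2)``:

    beta = sum(reference * noisy) / sum(reference^2)

computed as exact double-precision (pairwise-accumulated) sums over the
whole grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .wavelets import ImageGrid

__all__ = ["PredictionFactor", "linear_prediction_factor", "prediction_error"]


@dataclass(frozen=True)
class PredictionFactor:
    beta: float
    numerator: float
    denominator: float
    reference_id: str = ""

    def __post_init__(self) -> None:
        if not self.denominator > 0:
            raise InputError("denominator must be > 0")
        if not math.isfinite(self.beta):
            raise InputError("beta is not finite")


def _as_pixels(img: ImageGrid | np.ndarray) -> np.ndarray:
    if isinstance(img, ImageGrid):
        return img.pixels
    return np.asarray(img, dtype=np.float64)


def linear_prediction_factor(
    reference: ImageGrid | np.ndarray,
    noisy: ImageGrid | np.ndarray,
    reference_id: str = "",
) -> PredictionFactor:
    """Slope-through-origin estimate of the noisy image from the reference.

    Raises
    ------
    InputError
        On shape mismatch, or when the reference is identically zero (the
        denominator vanishes; supply a reference with nonzero energy).
    """
    ref = _as_pixels(reference)
    noi = _as_pixels(noisy)
    if ref.shape != noi.shape:
        raise InputError(f"shape mismatch: reference {ref.shape} vs noisy {noi.shape}")
    denom = float(np.sum(ref * ref))
    if denom == 0.0:
        raise InputError(
            "reference image is identically zero; beta is undefined "
            "(supply a reference with nonzero intensity)"
        )
    num = float(np.sum(ref * noi))
    return PredictionFactor(
        beta=num / denom, numerator=num, denominator=denom, reference_id=reference_id
    )


def prediction_error(
    reference: ImageGrid | np.ndarray,
    noisy: ImageGrid | np.ndarray,
    beta: float,
) -> np.ndarray:
    """Elementwise residual ``noisy - beta * reference``.

    With the optimal beta the residual is orthogonal to the reference:
    ``sum(residual * reference) ~ 0``.
    """
    ref = _as_pixels(reference)
    noi = _as_pixels(noisy)
    if ref.shape != noi.shape:
        raise InputError(f"shape mismatch: reference {ref.shape} vs noisy {noi.shape}")
    return noi - beta * ref
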