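"""Elementwise shrinkage rules for detail coefficients.

All four rules share the dead zone ``|w| < T -> 0`` and are odd functions of
``w``.  The adaptive rule tapers the shrink amount with a sine factor,

    sgn(w) * (|w| - sin(pi/2 * (T/|w|)^(beta*T)) * T)     for |w| >= T,

which is continuous at the threshold (the taper reaches 1 when |w| = T, so
the output passes through 0) and converges to the identity as |w| grows
(hard-threshold behavior away from T).  The taper lies in (0, 1], hence the
adaptive output is sandwiched between the soft and hard rules.

Every function accepts scalars or arrays; scalar input yields a float.  The
vectorized paths are bit-identical to the pointwise definitions for the
piecewise-linear rules, and within one ulp for the adaptive rule (whose
sin/pow evaluations may take different SIMD code paths per array length).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ShrinkageRule",
    "shrink_hard",
    "shrink_soft",
    "shrink_semisoft",
    "shrink_adaptive",
]


def _prepare(w, T: float):
    if T < 0 or not math.isfinite(T):
        raise ConfigurationError(f"threshold must be finite and >= 0, got {T}")
    arr = np.asarray(w, dtype=np.float64)
    return arr, arr.ndim == 0


def shrink_hard(w, T: float):
    """Keep ``w`` when ``|w| >= T``, zero otherwise."""
    arr, scalar = _prepare(w, T)
    out = np.where(np.abs(arr) >= T, arr, 0.0)
    return float(out) if scalar else out


def shrink_soft(w, T: float):
    """Shrink the magnitude by T on the kept branch: ``sgn(w)(|w| - T)``."""
    arr, scalar = _prepare(w, T)
    out = np.where(np.abs(arr) >= T, np.sign(arr) * (np.abs(arr) - T), 0.0)
    return float(out) if scalar else out


def shrink_semisoft(w, T: float, alpha: float):
    """Interpolate hard (alpha=0) and soft (alpha=1): ``sgn(w)(|w| - alpha*T)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in [0, 1], got {alpha}")
    arr, scalar = _prepare(w, T)
    out = np.where(np.abs(arr) >= T, np.sign(arr) * (np.abs(arr) - alpha * T), 0.0)
    return float(out) if scalar else out


def shrink_adaptive(w, T: float, beta: float):
    """Sine-tapered shrinkage; identity when ``T == 0``.

    The exponent is the product ``beta * T``.  Because ``T/|w| <= 1`` on the
    kept branch the power never overflows; at ``|w| = T`` the taper equals
    ``sin(pi/2) = 1`` so the output is exactly 0.
    """
    if not beta > 0:
        raise ConfigurationError(f"beta must be > 0, got {beta}")
    arr, scalar = _prepare(w, T)
    if T == 0.0:
        out = arr + 0.0
        return float(out) if scalar else out
    absw = np.abs(arr)
    kept = absw >= T
    # evaluate the power only on the kept branch to avoid 0**0 and divide-by-0
    safe = np.where(kept, absw, T)
    taper = np.sin(0.5 * np.pi * (T / safe) ** (beta * T))
    out = np.where(kept, np.sign(arr) * (absw - taper * T), 0.0)
    return float(out) if scalar else out


@dataclass(frozen=True)
class ShrinkageRule:
    """A configured rule that can be applied to scalars or coefficient grids."""

    kind: Literal["hard", "soft", "semisoft", "adaptive"]
    T: float
    alpha: float = 0.5
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("hard", "soft", "semisoft", "adaptive"):
            raise ConfigurationError(f"unknown shrinkage rule {self.kind!r}")
        if self.T < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.T}")
        if self.kind == "semisoft" and not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.kind == "adaptive" and not self.beta > 0:
            raise ConfigurationError(f"beta must be > 0, got {self.beta}")

    def apply(self, w):
        if self.kind == "hard":
            return shrink_hard(w, self.T)
        if self.kind == "soft":
            return shrink_soft(w, self.T)
        if self.kind == "semisoft":
            return shrink_semisoft(w, self.T, self.alpha)
        return shrink_adaptive(w, self.T, self.beta)

    __call__ = apply
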