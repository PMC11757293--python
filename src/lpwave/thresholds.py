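"""Noise-level estimation and threshold values.

Three estimators are provided:

* the universal (VisuShrink) threshold ``T = sigma * sqrt(2 log N)``,
* the BayesShrink per-subband threshold ``T = sigma^2 / sigma_x``,
* the prediction-weighted, level-dependent threshold
  ``T_j = sigma * sqrt(2 log N) * log(1 + j) * beta``.

The robust noise estimate is the median absolute coefficient of the finest
diagonal subband divided by 0.6745.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import ConfigurationError, InputError

MAD_SCALE = 0.6745  # Gaussian consistency constant for the median estimator

LogBase = Literal["natural", "ten"]
BetaParse = Literal["product", "divide_beta"]

__all__ = [
    "MAD_SCALE",
    "NoiseEstimate",
    "ThresholdSpec",
    "ThresholdValue",
    "estimate_sigma",
    "universal_threshold",
    "bayes_threshold",
    "proposed_threshold",
]


@dataclass(frozen=True)
class NoiseEstimate:
    sigma: float
    source: str = "HH1-median"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.sigma) and self.sigma >= 0):
            raise InputError(f"sigma must be finite and >= 0, got {self.sigma}")


@dataclass(frozen=True)
class ThresholdSpec:
    """Configuration for threshold computation.

    ``n_pixels`` is the signal length N (total image pixels by default);
    ``level`` and ``beta`` only matter for the proposed method.
    """

    method: Literal["universal", "bayes", "proposed"]
    n_pixels: int = 0
    level: int = 1
    beta: float = 1.0
    log_base: LogBase = "natural"
    beta_parse: BetaParse = "product"

    def __post_init__(self) -> None:
        if self.method not in ("universal", "bayes", "proposed"):
            raise ConfigurationError(f"unknown threshold method {self.method!r}")
        if self.method == "proposed" and not self.beta > 0:
            raise ConfigurationError(f"beta must be > 0, got {self.beta}")
        if self.level < 1:
            raise ConfigurationError(f"level must be >= 1, got {self.level}")


@dataclass(frozen=True)
class ThresholdValue:
    """A non-negative cutoff, tagged with the level it applies to (0 = global)
    and whether it is the BayesShrink kill-all sentinel."""

    value: float
    level: int = 0
    kill_all: bool = False
    parse: BetaParse | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value >= 0):
            raise InputError(f"threshold must be finite and >= 0, got {self.value}")


def _log(x: float, base: LogBase) -> float:
    return math.log10(x) if base == "ten" else math.log(x)


def estimate_sigma(hh1: np.ndarray) -> NoiseEstimate:
    """Robust noise standard deviation from the finest diagonal subband:
    ``median(|w|) / 0.6745``.

    Invariant to sign flips and permutations of the coefficients.
    """
    hh1 = np.asarray(hh1, dtype=np.float64)
    if hh1.size == 0:
        raise InputError("empty HH1 subband")
    if not np.all(np.isfinite(hh1)):
        raise InputError("HH1 subband contains non-finite coefficients")
    sigma = float(np.median(np.abs(hh1)) / MAD_SCALE)
    return NoiseEstimate(sigma=sigma, source="HH1-median")


def universal_threshold(sigma: float, n_pixels: int, log_base: LogBase = "natural") -> ThresholdValue:
    """Universal (VisuShrink) threshold ``T = sigma * sqrt(2 log N)``."""
    if sigma < 0 or not math.isfinite(sigma):
        raise InputError(f"sigma must be finite and >= 0, got {sigma}")
    if n_pixels < 2:
        raise InputError(f"n_pixels must be >= 2, got {n_pixels}")
    return ThresholdValue(value=sigma * math.sqrt(2.0 * _log(n_pixels, log_base)))


def bayes_threshold(sigma: float, subband: np.ndarray) -> ThresholdValue:
    """BayesShrink subband threshold ``T = sigma^2 / sigma_x`` with
    ``sigma_x = sqrt(max(mean(w^2) - sigma^2, 0))``.

    When the signal-deviation estimate vanishes the entire subband is deemed
    noise; the returned value is ``max|w| + 1`` with ``kill_all`` set so any
    downstream shrinkage rule zeroes the whole subband.
    """
    subband = np.asarray(subband, dtype=np.float64)
    if subband.size == 0:
        raise InputError("empty subband")
    if sigma < 0 or not math.isfinite(sigma):
        raise InputError(f"sigma must be finite and >= 0, got {sigma}")
    var_y = float(np.mean(subband ** 2))
    var_x = max(var_y - sigma ** 2, 0.0)
    if var_x == 0.0:
        if sigma == 0.0:
            return ThresholdValue(value=0.0)
        return ThresholdValue(value=float(np.max(np.abs(subband))) + 1.0, kill_all=True)
    return ThresholdValue(value=sigma ** 2 / math.sqrt(var_x))


def proposed_threshold(
    sigma: float,
    n_pixels: int,
    level: int,
    beta: float,
    log_base: LogBase = "natural",
    beta_parse: BetaParse = "product",
) -> ThresholdValue:
    """Level- and prediction-weighted threshold.

    Default parse: ``T_j = sigma * sqrt(2 log N) * log(1 + j) * beta``; the
    ``divide_beta`` parse divides by beta instead.  Either way the result is a
    pure scaling of the universal threshold.
    """
    if not beta > 0:
        raise ConfigurationError(f"beta must be > 0, got {beta}")
    if level < 1:
        raise ConfigurationError(f"level must be >= 1, got {level}")
    base = universal_threshold(sigma, n_pixels, log_base).value
    scale = _log(1.0 + level, log_base)
    if beta_parse == "product":
        value = base * scale * beta
    elif beta_parse == "divide_beta":
        value = base * scale / beta
    else:
        raise ConfigurationError(f"unknown beta_parse {beta_parse!r}")
    return ThresholdValue(value=value, level=level, parse=beta_parse)


def compute_threshold(spec: ThresholdSpec, sigma: float, subband: np.ndarray | None = None) -> ThresholdValue:
    """Dispatch on ``spec.method``; `subband` is required for BayesShrink."""
    if spec.method == "universal":
        return universal_threshold(sigma, spec.n_pixels, spec.log_base)
    if spec.method == "bayes":
        if subband is None:
            raise ConfigurationError("bayes threshold requires the subband coefficients")
        return bayes_threshold(sigma, subband)
    return proposed_threshold(
        sigma, spec.n_pixels, spec.level, spec.beta, spec.log_base, spec.beta_parse
    )
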