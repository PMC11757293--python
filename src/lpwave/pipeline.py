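"""End-to-end denoising, the benchmark harness, and image/CSV I/O.

The denoising chain is: multilevel analysis -> robust sigma from the finest
diagonal subband -> threshold (global, per-subband, or per-level depending
on the method) -> shrinkage of every detail subband -> synthesis.

Method presets:

* ``visushrink``  = universal threshold + soft rule
* ``bayesshrink`` = per-subband Bayes threshold + soft rule
* ``proposed``    = prediction-weighted per-level threshold + adaptive rule
  (requires a same-size reference image for the slope factor beta)
"""

from __future__ import annotations

import csv
import logging
import math
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, LPWaveError
from .metrics import MetricsReport, report
from .prediction import linear_prediction_factor
from .shrink import ShrinkageRule
from .synthetic import NoiseSpec, add_gaussian_noise
from .thresholds import bayes_threshold, estimate_sigma, proposed_threshold, universal_threshold
from .wavelets import DETAIL_KEYS, ImageGrid, decompose, reconstruct

logger = logging.getLogger("lpwave")

CSV_COLUMNS = ["image_id", "method", "noise_variance", "replicate", "seed", "mse", "psnr_db", "ssim"]

__all__ = [
    "CSV_COLUMNS",
    "DenoiseConfig",
    "BenchmarkRecord",
    "METHOD_PRESETS",
    "denoise",
    "run_benchmark",
    "summarize_records",
    "read_image",
    "write_image",
    "write_records_csv",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Full configuration of one denoising method."""

    name: str = "custom"
    wavelet_name: str = "bior3.9"
    levels: int = 3
    threshold_method: str = "universal"       # universal | bayes | proposed
    shrink_method: str = "soft"               # hard | soft | semisoft | adaptive
    alpha: float = 0.5
    log_base: str = "natural"
    beta_parse: str = "product"
    n_convention: str = "image"               # image | subband
    clip_output: bool = False

    def __post_init__(self) -> None:
        if self.threshold_method not in ("universal", "bayes", "proposed"):
            raise ConfigurationError(f"unknown threshold method {self.threshold_method!r}")
        if self.shrink_method not in ("hard", "soft", "semisoft", "adaptive"):
            raise ConfigurationError(f"unknown shrink method {self.shrink_method!r}")
        if self.levels < 1:
            raise ConfigurationError(f"levels must be >= 1, got {self.levels}")
        if self.n_convention not in ("image", "subband"):
            raise ConfigurationError(f"unknown N convention {self.n_convention!r}")

    @property
    def needs_reference(self) -> bool:
        return self.threshold_method == "proposed" or self.shrink_method == "adaptive"


METHOD_PRESETS: dict[str, DenoiseConfig] = {
    "visushrink": DenoiseConfig(name="visushrink", threshold_method="universal", shrink_method="soft"),
    "bayesshrink": DenoiseConfig(name="bayesshrink", threshold_method="bayes", shrink_method="soft"),
    "proposed": DenoiseConfig(name="proposed", threshold_method="proposed", shrink_method="adaptive"),
}


@dataclass(frozen=True)
class BenchmarkRecord:
    image_id: str
    method: str
    noise_variance: float
    replicate: int
    seed: int
    mse: float = math.nan
    psnr_db: float = math.nan
    ssim: float = math.nan
    error: str = ""


def denoise(
    noisy: ImageGrid,
    config: DenoiseConfig,
    reference: ImageGrid | None = None,
) -> ImageGrid:
    """Run the full shrinkage chain on `noisy` under `config`.

    `reference` is mandatory for the proposed threshold and the adaptive
    rule — it supplies the prediction slope beta — and must match the noisy
    image's shape.
    """
    if config.needs_reference:
        if reference is None:
            raise ConfigurationError(
                f"method {config.name!r} ({config.threshold_method}/{config.shrink_method}) "
                "requires a reference image for the prediction factor"
            )
        if reference.pixels.shape != noisy.pixels.shape:
            raise InputError(
                f"reference shape {reference.pixels.shape} != noisy shape {noisy.pixels.shape}"
            )

    pyramid = decompose(noisy, config.wavelet_name, config.levels)
    sigma = estimate_sigma(pyramid.hh1).sigma

    beta = 1.0
    if config.needs_reference:
        beta = linear_prediction_factor(reference, noisy).beta
        if beta <= 0:
            raise ConfigurationError(
                f"non-positive prediction factor beta={beta:.6g}; the adaptive "
                "method needs a positively correlated reference"
            )

    def n_for(subband: np.ndarray) -> int:
        return noisy.n_pixels if config.n_convention == "image" else subband.size

    new_details: list[dict[str, np.ndarray]] = []
    for idx, bands in enumerate(pyramid.details):
        level = idx + 1
        out: dict[str, np.ndarray] = {}
        for key in DETAIL_KEYS:
            grid = bands[key]
            if config.threshold_method == "universal":
                T = universal_threshold(sigma, n_for(grid), config.log_base).value
            elif config.threshold_method == "bayes":
                T = bayes_threshold(sigma, grid).value
            else:
                T = proposed_threshold(
                    sigma, n_for(grid), level, beta, config.log_base, config.beta_parse
                ).value
            rule = ShrinkageRule(config.shrink_method, T, alpha=config.alpha, beta=beta)
            out[key] = rule.apply(grid)
        new_details.append(out)

    result = reconstruct(replace(pyramid, details=new_details))
    if config.clip_output:
        result = ImageGrid(
            np.clip(result.pixels, 0.0, noisy.dynamic_range),
            dynamic_range=noisy.dynamic_range,
        )
    return result


def _cell_seed(base_seed: int, image_id: str, variance: float, replicate: int) -> int:
    """Deterministic, platform-independent per-cell seed."""
    tag = f"{image_id}|{variance:.10g}|{replicate}".encode()
    return (base_seed + zlib.crc32(tag)) % (2 ** 31)


def run_benchmark(
    images: Sequence[ImageGrid],
    variances: Sequence[float],
    methods: Sequence[DenoiseConfig],
    reps: int = 1,
    seed: int = 0,
    image_ids: Sequence[str] | None = None,
    ssim_mode: str = "global",
) -> list[BenchmarkRecord]:
    """Full factorial images x variances x methods x replicates.

    Each (image, variance, replicate) cell draws one noisy realization that
    is shared by all methods; the clean image serves as the reference for
    reference-requiring methods and as the ground truth for the metrics
    (computed on the 0-255 scale).  Single-cell failures are logged and
    recorded as failed rows.
    """
    if not images or not variances or not methods:
        raise InputError("images, variances and methods must be non-empty")
    if reps < 1:
        raise InputError(f"reps must be >= 1, got {reps}")
    if image_ids is None:
        image_ids = [f"image{k + 1}" for k in range(len(images))]
    if len(image_ids) != len(images):
        raise InputError("one image_id per image is required")

    records: list[BenchmarkRecord] = []
    for img_id, clean in zip(image_ids, images):
        for variance in variances:
            for rep in range(reps):
                cell_seed = _cell_seed(seed, img_id, variance, rep)
                noisy = add_gaussian_noise(clean, NoiseSpec(variance=variance, seed=cell_seed))
                for cfg in methods:
                    base = BenchmarkRecord(
                        image_id=img_id, method=cfg.name, noise_variance=variance,
                        replicate=rep, seed=cell_seed,
                    )
                    try:
                        out = denoise(noisy, cfg, reference=clean if cfg.needs_reference else None)
                        m: MetricsReport = report(clean, out, ssim_mode=ssim_mode)
                        records.append(replace(base, mse=m.mse, psnr_db=m.psnr_db, ssim=m.ssim))
                    except LPWaveError as exc:
                        logger.error("cell (%s, %s, %g, rep %d) failed: %s",
                                     img_id, cfg.name, variance, rep, exc)
                        records.append(replace(base, error=str(exc)))
    return records


def summarize_records(records: Iterable[BenchmarkRecord]) -> pd.DataFrame:
    """Per-(method, variance) means of the three metrics, one metric block
    per row group — the layout used for reporting."""
    rows = [r.__dict__ for r in records if not r.error]
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["image_id", "method", "noise_variance"])[["mse", "psnr_db", "ssim"]]
        .mean()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# I/O

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path) -> ImageGrid:
    """Read an 8/16-bit grayscale PNG or TIFF; RGB input is converted to
    luminance with a logged warning."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio raises assorted types for bad formats
        raise InputError(f"cannot read image {path} ({path.suffix or 'no extension'}): {exc}") from exc
    arr = np.asarray(raw)
    if arr.ndim == 3:
        logger.warning("converting %d-channel image %s to grayscale by luminance", arr.shape[2], path)
        arr = arr[..., :3].astype(np.float64) @ _LUMA
        if raw.dtype == np.uint8:
            arr = np.rint(arr)
    if raw.dtype == np.uint8:
        L = 255.0
    elif raw.dtype == np.uint16:
        L = 65535.0
    else:
        L = 1.0
    return ImageGrid(arr.astype(np.float64), dynamic_range=L)


def write_image(image: ImageGrid, path: str | Path) -> None:
    """Write an 8-bit grayscale PNG/TIFF, clipping to the valid display range."""
    path = Path(path)
    scaled = np.clip(image.pixels * (255.0 / image.dynamic_range), 0.0, 255.0)
    iio.imwrite(path, np.rint(scaled).astype(np.uint8))


def _fmt(x: float) -> str:
    if math.isnan(x):
        return ""
    if math.isinf(x):
        return "inf"
    return repr(x)


def write_records_csv(records: Iterable[BenchmarkRecord], path: str | Path) -> None:
    """Serialize records with the fixed column header; byte-reproducible."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow([
                r.image_id, r.method, f"{r.noise_variance:.10g}", r.replicate, r.seed,
                _fmt(r.mse), _fmt(r.psnr_db), _fmt(r.ssim),
            ])
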