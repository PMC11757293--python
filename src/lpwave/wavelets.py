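"""Multilevel 2-D discrete wavelet transform with symmetric boundary extension.

The separable transform is implemented directly on top of the shipped filter
banks (see :mod:`lpwave._filters`).  Boundary handling is half-sample
symmetric extension, the common default for biorthogonal bases, and the
transform is *expansive*: a length-``n`` signal filtered with a length-``F``
filter yields ``(n + F - 1) // 2`` coefficients per channel, which guarantees
perfect reconstruction for arbitrary signal lengths.

Subband naming: ``HL`` is high-pass along x (columns) / low-pass along y,
``LH`` the converse, ``HH`` the diagonal band.  Level 1 is the finest scale;
levels increase toward coarser scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._filters import available_wavelets, filter_bank
from .errors import ConfigurationError, DepthError, InputError, NumericalError, StructuralError

DETAIL_KEYS = ("HL", "LH", "HH")

__all__ = [
    "DETAIL_KEYS",
    "ImageGrid",
    "WaveletPyramid",
    "decompose",
    "reconstruct",
    "map_details",
]


@dataclass(frozen=True)
class ImageGrid:
    """A 2-D intensity grid with a declared dynamic range.

    Parameters
    ----------
    pixels : ndarray
        Real-valued 2-D array; stored as float64.
    dynamic_range : float
        Peak representable intensity ``L`` (255 for 8-bit data, 1.0 for
        normalized data).  Used when scaling for metric evaluation.
    """

    pixels: np.ndarray
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise InputError(f"expected a 2-D grid, got ndim={px.ndim}")
        if px.size == 0:
            raise InputError("empty image grid")
        if not np.all(np.isfinite(px)):
            raise InputError("image contains non-finite intensities")
        if not (self.dynamic_range > 0):
            raise InputError(f"dynamic_range must be > 0, got {self.dynamic_range}")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.pixels.size


@dataclass
class WaveletPyramid:
    """Approximation plus per-level {HL, LH, HH} detail subbands.

    ``details[0]`` is the finest level (level 1).  ``input_shapes[j]`` records
    the spatial shape of the grid that was decomposed at level ``j + 1``,
    which the inverse transform needs to trim the expansive convolutions.
    """

    wavelet_name: str
    levels: int
    approx: np.ndarray
    details: list[dict[str, np.ndarray]]
    input_shapes: list[tuple[int, int]]
    dynamic_range: float = 1.0

    def __post_init__(self) -> None:
        if len(self.details) != self.levels:
            raise StructuralError(
                f"levels={self.levels} but {len(self.details)} detail entries"
            )
        if len(self.input_shapes) != self.levels:
            raise StructuralError("one input shape per level is required")

    def detail(self, level: int, key: str) -> np.ndarray:
        """Detail subband at 1-based `level`; key in {'HL','LH','HH'}."""
        return self.details[level - 1][key]

    @property
    def hh1(self) -> np.ndarray:
        """Finest diagonal subband (used for noise estimation)."""
        return self.details[0]["HH"]


def _get_filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    try:
        return filter_bank(wavelet_name)
    except KeyError:
        raise ConfigurationError(
            f"unknown wavelet {wavelet_name!r}; available: {', '.join(available_wavelets())}"
        ) from None


def _analysis_axis(arr: np.ndarray, lo: np.ndarray, hi: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Single-level analysis along `axis`: symmetric-extend, filter, downsample."""
    F = lo.size
    arr = np.moveaxis(arr, axis, -1)
    pad = [(0, 0)] * (arr.ndim - 1) + [(F - 1, F - 1)]
    ext = np.pad(arr, pad, mode="symmetric")
    win = sliding_window_view(ext, F, axis=-1)[..., 1::2, :]
    a = win @ lo[::-1]
    d = win @ hi[::-1]
    return np.moveaxis(a, -1, axis), np.moveaxis(d, -1, axis)


def _synthesis_axis(a: np.ndarray, d: np.ndarray, rlo: np.ndarray, rhi: np.ndarray,
                    axis: int, out_len: int) -> np.ndarray:
    """Single-level synthesis along `axis`: upsample, filter, sum, trim."""
    F = rlo.size
    a = np.moveaxis(a, axis, -1)
    d = np.moveaxis(d, axis, -1)
    n = a.shape[-1]
    up = np.zeros(a.shape[:-1] + (2 * n,), dtype=np.float64)
    up[..., ::2] = a
    up_d = np.zeros_like(up)
    up_d[..., ::2] = d
    pad = [(0, 0)] * (up.ndim - 1) + [(F - 1, F - 1)]
    ext_a = np.pad(up, pad)
    ext_d = np.pad(up_d, pad)
    full = sliding_window_view(ext_a, F, axis=-1) @ rlo[::-1]
    full = full + sliding_window_view(ext_d, F, axis=-1) @ rhi[::-1]
    y = full[..., F - 2: F - 2 + out_len]
    return np.moveaxis(y, -1, axis)


def decompose(image: ImageGrid, wavelet_name: str = "bior3.9", levels: int = 3) -> WaveletPyramid:
    """Multilevel 2-D wavelet analysis of `image`.

    Parameters
    ----------
    image : ImageGrid
    wavelet_name : str
        One of the shipped bases (default ``bior3.9``).
    levels : int
        Decomposition depth; level 1 is the finest scale.

    Raises
    ------
    DepthError
        If the image is too small for the requested depth.
    ConfigurationError
        For an unknown wavelet name.
    """
    if levels < 1:
        raise ConfigurationError(f"levels must be >= 1, got {levels}")
    lo, hi, _, _ = _get_filters(wavelet_name)
    if min(image.height, image.width) < 2 ** levels:
        raise DepthError(
            f"image {image.height}x{image.width} too small for {levels} levels "
            f"(needs at least {2 ** levels} pixels per side)"
        )
    approx = image.pixels
    details: list[dict[str, np.ndarray]] = []
    shapes: list[tuple[int, int]] = []
    for _ in range(levels):
        shapes.append(approx.shape)
        lx, hx = _analysis_axis(approx, lo, hi, axis=1)
        ll, lh = _analysis_axis(lx, lo, hi, axis=0)
        hl, hh = _analysis_axis(hx, lo, hi, axis=0)
        details.append({"HL": hl, "LH": lh, "HH": hh})
        approx = ll
    return WaveletPyramid(
        wavelet_name=wavelet_name,
        levels=levels,
        approx=approx,
        details=details,
        input_shapes=shapes,
        dynamic_range=image.dynamic_range,
    )


def reconstruct(pyramid: WaveletPyramid) -> ImageGrid:
    """Inverse multilevel transform; exact inverse of :func:`decompose`
    when the coefficients are unmodified."""
    _, _, rlo, rhi = _get_filters(pyramid.wavelet_name)
    approx = pyramid.approx
    for level in range(pyramid.levels, 0, -1):
        bands = pyramid.details[level - 1]
        h, w = pyramid.input_shapes[level - 1]
        hl, lh, hh = bands["HL"], bands["LH"], bands["HH"]
        if not (approx.shape == lh.shape and hl.shape == hh.shape):
            raise StructuralError(
                f"inconsistent subband shapes at level {level}: "
                f"approx {approx.shape}, LH {lh.shape}, HL {hl.shape}, HH {hh.shape}"
            )
        # column-length after the x-direction analysis of an (h, w) grid
        mid_h = h
        lx = _synthesis_axis(approx, lh, rlo, rhi, axis=0, out_len=mid_h)
        hx = _synthesis_axis(hl, hh, rlo, rhi, axis=0, out_len=mid_h)
        approx = _synthesis_axis(lx, hx, rlo, rhi, axis=1, out_len=w)
    if not np.all(np.isfinite(approx)):
        raise NumericalError("reconstruction produced non-finite values")
    return ImageGrid(approx, dynamic_range=pyramid.dynamic_range)


def map_details(
    pyramid: WaveletPyramid,
    rule: Callable[..., np.ndarray],
    per_level: bool = False,
) -> WaveletPyramid:
    """Apply `rule` elementwise to every detail subband; the approximation
    band is left untouched.

    `rule` is called with the coefficient array (and the 1-based level index
    when `per_level` is set) and should return an array of the same shape;
    plain scalar functions are lifted automatically.
    """
    new_details: list[dict[str, np.ndarray]] = []
    for idx, bands in enumerate(pyramid.details):
        level = idx + 1
        out_bands: dict[str, np.ndarray] = {}
        for key, grid in bands.items():
            args = (grid, level) if per_level else (grid,)
            try:
                res = np.asarray(rule(*args), dtype=np.float64)
                if res.shape != grid.shape:
                    raise TypeError
            except (TypeError, ValueError):
                res = np.vectorize(rule, otypes=[np.float64])(*args)
            if not np.all(np.isfinite(res)):
                raise NumericalError(
                    f"rule produced non-finite coefficients in subband {key} at level {level}"
                )
            out_bands[key] = res
        new_details.append(out_bands)
    return replace(pyramid, approx=pyramid.approx.copy(), details=new_details)
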