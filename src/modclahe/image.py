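"""Grayscale image container and basic raster I/O.

Every stage of the enhancement pipeline consumes and produces a
:class:`GrayImage`: a 2-D raster of integer intensities in ``[0, L-1]``
together with the number of intensity levels ``L`` (256 for ordinary 8-bit
radiographs, but a parameter throughout so small toy images with e.g. L=4
are exactly testable).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image as _PILImage
from scipy import ndimage as _ndi

__all__ = ["GrayImage", "read_image", "write_image", "resize_image"]


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer, halves away from zero.

    All intensities in this package are non-negative, for which this is
    ``floor(x + 0.5)``.
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with an explicit number of intensity levels.

    Parameters
    ----------
    pixels
        2-D integer array; every value must lie in ``[0, levels - 1]``.
    levels
        Number of representable intensity levels ``L`` (default 256).
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        if arr.size == 0:
            raise ValueError("image must contain at least one pixel")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("pixel values must be integral")
            arr = arr.astype(np.int64)
        if arr.min() < 0 or arr.max() > self.levels - 1:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        dtype = np.uint8 if self.levels <= 256 else np.uint16
        object.__setattr__(self, "pixels", np.ascontiguousarray(arr, dtype=dtype))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def n_rows(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def n_cols(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.size)

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrayImage):
            return NotImplemented
        return self.levels == other.levels and np.array_equal(self.pixels, other.pixels)


def read_image(path: str | os.PathLike, levels: int = 256) -> GrayImage:
    """Read a PNG/JPEG raster as a :class:`GrayImage`.

    RGB inputs are converted by the unweighted channel mean (the radiograph
    datasets this targets are nominally grayscale; channel weighting is
    irrelevant). Values are clamped to ``[0, levels - 1]``.
    """
    try:
        with _PILImage.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError as exc:
        raise IOError(f"cannot read image file: {path!s}") from exc
    except Exception as exc:  # PIL raises UnidentifiedImageError / OSError
        raise IOError(f"cannot decode image file: {path!s}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized raster: {path!s}")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = round_half_away(arr.mean(axis=2))
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster shape {arr.shape} in {path!s}")
    arr = np.clip(arr, 0, levels - 1).astype(np.int64)
    return GrayImage(arr, levels=levels)


def write_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write as 8-bit PNG (lossless; avoids JPEG recompression artifacts)."""
    if img.levels > 256:
        raise ValueError("PNG output supports at most 256 levels")
    _PILImage.fromarray(img.pixels.astype(np.uint8), mode="L").save(path, format="PNG")


def resize_image(img: GrayImage, target: tuple[int, int]) -> GrayImage:
    """Bilinear resample to ``target = (rows, cols)``.

    Uses the align-corners convention (pixel centers at integer coordinates,
    corner pixels map to corner pixels); outputs are rounded half away from
    zero and clamped to the intensity range.
    """
    rows, cols = int(target[0]), int(target[1])
    if rows < 1 or cols < 1:
        raise ValueError(f"target dimensions must be >= 1, got {target}")
    if (rows, cols) == img.shape:
        return GrayImage(img.pixels.copy(), levels=img.levels)
    m, n = img.shape
    # target grid mapped linearly onto the source corner-to-corner span
    rr = np.full(rows, (m - 1) / 2.0) if rows == 1 else np.linspace(0.0, m - 1, rows)
    cc = np.full(cols, (n - 1) / 2.0) if cols == 1 else np.linspace(0.0, n - 1, cols)
    grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
    out = _ndi.map_coordinates(
        img.astype_float(), [grid_r, grid_c], order=1, mode="nearest"
    )
    out = np.clip(round_half_away(out), 0, img.levels - 1).astype(np.int64)
    return GrayImage(out, levels=img.levels)
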