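"""No-reference quality scoring, noise variance and contrast-to-noise ratio.

The parameter search ranks enhanced images by a no-reference quality score
(lower = better). Scoring goes through a pluggable backend registry: a
BRISQUE-style scorer built on a pretrained natural-scene-statistics model
can be attached at runtime via :func:`register_backend`, while the shipped
``"surrogate"`` backend is a deterministic stand-in that needs no trained
model — it penalizes low histogram entropy (poor contrast) and residual
noise in homogeneous regions:

    S = (1 - H_img / log2 L) + lambda * NV / (L - 1)^2

where ``H_img`` is the global histogram entropy and ``NV`` the mean local
variance over low-gradient (homogeneous) windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage as _ndi

from .histogram import compute_histogram, normalize_histogram, shannon_entropy
from .image import GrayImage, read_image

__all__ = [
    "QualityScore",
    "RegionSpec",
    "ConfigurationError",
    "register_backend",
    "registered_backends",
    "brisque_score",
    "surrogate_score",
    "noise_variance_homogeneous",
    "cnr",
    "dataset_mean_score",
]


class ConfigurationError(KeyError):
    """An unknown quality backend was requested."""


@dataclass(frozen=True)
class QualityScore:
    """A no-reference quality value; lower always means better here."""

    value: float
    backend: str
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError(f"quality score must be finite, got {self.value}")


@dataclass(frozen=True)
class RegionSpec:
    """Rectangular ROI and background patches, as (row, col, height, width)."""

    roi: tuple[int, int, int, int]
    background: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for name, rect in (("roi", self.roi), ("background", self.background)):
            r, c, h, w = rect
            if h < 1 or w < 1 or r < 0 or c < 0:
                raise ValueError(f"{name} rectangle {rect} is degenerate")
        if _rects_overlap(self.roi, self.background):
            raise ValueError("roi and background regions must not overlap")

    def validate_within(self, img: GrayImage) -> None:
        m, n = img.shape
        for name, (r, c, h, w) in (("roi", self.roi), ("background", self.background)):
            if r + h > m or c + w > n:
                raise ValueError(f"{name} rectangle exceeds image bounds {(m, n)}")

    def extract(self, img: GrayImage, which: str) -> np.ndarray:
        r, c, h, w = self.roi if which == "roi" else self.background
        return img.pixels[r : r + h, c : c + w].astype(np.float64)


def _rects_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ar, ac, ah, aw = a
    br, bc, bh, bw = b
    return ar < br + bh and br < ar + ah and ac < bc + bw and bc < ac + aw


# --------------------------------------------------------------------------
# backend registry
# --------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[[GrayImage], float]] = {}


def register_backend(name: str, fn: Callable[[GrayImage], float]) -> None:
    """Register a scoring callable ``fn(img) -> float`` under ``name``."""
    _BACKENDS[name] = fn


def registered_backends() -> list[str]:
    return sorted(_BACKENDS)


def brisque_score(img: GrayImage, backend: str = "surrogate") -> QualityScore:
    """Score an image with a registered no-reference quality backend."""
    if backend not in _BACKENDS:
        raise ConfigurationError(
            f"unknown quality backend {backend!r}; registered: {registered_backends()}"
        )
    return QualityScore(float(_BACKENDS[backend](img)), backend=backend)


# --------------------------------------------------------------------------
# deterministic surrogate
# --------------------------------------------------------------------------

def surrogate_score(img: GrayImage, lam: float = 1.0, window: int = 7) -> QualityScore:
    """Deterministic contrast + noise penalty; lower = better.

    The first term is 1 minus the normalized global histogram entropy (0 for
    a perfectly spread histogram, 1 for a constant image); the second is the
    homogeneous-region noise variance scaled by the squared dynamic range.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    probs = normalize_histogram(compute_histogram(img), img.n_pixels)
    h_img = shannon_entropy(probs)
    contrast_term = 1.0 - h_img / np.log2(img.levels)
    nv = noise_variance_homogeneous(img, window=window)
    value = contrast_term + lam * nv / (img.levels - 1) ** 2
    return QualityScore(value, backend="surrogate")


register_backend("surrogate", lambda img: surrogate_score(img).value)


def noise_variance_homogeneous(img: GrayImage, window: int = 7) -> float:
    """Mean local variance over homogeneous (low-gradient) windows.

    Local variance and local mean gradient magnitude are computed in every
    fully-contained ``window x window`` sliding window; windows whose mean
    gradient magnitude falls in the lowest quartile count as homogeneous,
    and their mean local variance is returned.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    m, n = img.shape
    if window > m or window > n:
        raise ValueError(f"window {window} does not fit in image of shape {(m, n)}")
    p = img.astype_float()
    local_mean = _ndi.uniform_filter(p, size=window)
    local_sq = _ndi.uniform_filter(p * p, size=window)
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    gy, gx = np.gradient(p)
    gmag = np.hypot(gy, gx)
    local_grad = _ndi.uniform_filter(gmag, size=window)
    h = window // 2
    valid = (slice(h, m - h), slice(h, n - h))
    grad_valid = local_grad[valid]
    var_valid = local_var[valid]
    threshold = np.percentile(grad_valid, 25.0)
    mask = grad_valid <= threshold
    return float(var_valid[mask].mean())


def cnr(img: GrayImage, regions: RegionSpec) -> float:
    """Contrast-to-noise ratio |mean(roi) - mean(bg)| / std(bg)."""
    regions.validate_within(img)
    roi = regions.extract(img, "roi")
    bg = regions.extract(img, "background")
    bg_std = float(bg.std())
    if bg_std == 0:
        raise ZeroDivisionError("background standard deviation is zero; CNR undefined")
    return abs(float(roi.mean()) - float(bg.mean())) / bg_std


def dataset_mean_score(
    paths: Sequence, backend: str = "surrogate", levels: int = 256
) -> tuple[float, list[tuple[str, float]]]:
    """Arithmetic mean of per-image scores over a list of image paths.

    Returns ``(mean, per_image)`` where ``per_image`` is a list of
    ``(path, score)`` pairs for logging/reporting.
    """
    if len(paths) == 0:
        raise ValueError("dataset_mean_score requires at least one image")
    per_image: list[tuple[str, float]] = []
    for path in paths:
        if isinstance(path, GrayImage):
            score = brisque_score(path, backend).value
            per_image.append(("<in-memory>", score))
        else:
            score = brisque_score(read_image(path, levels=levels), backend).value
            per_image.append((str(path), score))
    mean = float(np.mean([s for _, s in per_image]))
    return mean, per_image
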