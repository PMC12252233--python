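"""Histograms, global histogram equalization and entropy.

These are the primitives the tile-based enhancement is assembled from:
the discrete intensity histogram h(r_k) = n_k, its normalization
p(r_k) = n_k / (M N), the cumulative equalization transfer
s_k = round((L-1) * sum_{j<=k} p_j), and Shannon entropy in bits.

Histogram counts are carried as float arrays because contrast-limited
clipping and redistribution produce fractional per-bin mass.
"""

from __future__ import annotations

import numpy as np

from .image import GrayImage, round_half_away

__all__ = [
    "compute_histogram",
    "normalize_histogram",
    "equalization_transfer",
    "apply_global_he",
    "shannon_entropy",
]


def compute_histogram(region: GrayImage | np.ndarray, levels: int | None = None) -> np.ndarray:
    """Per-bin pixel counts of an image or rectangular sub-region.

    Returns a length-``levels`` float array whose sum equals the number of
    pixels in the region.
    """
    if isinstance(region, GrayImage):
        arr = region.pixels
        levels = region.levels if levels is None else levels
    else:
        arr = np.asarray(region)
        if levels is None:
            raise ValueError("levels must be given for a bare array region")
    if arr.size == 0:
        raise ValueError("cannot compute the histogram of an empty region")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=levels)
    if counts.size > levels:
        raise ValueError(f"values exceed levels={levels}")
    return counts.astype(np.float64)


def normalize_histogram(counts: np.ndarray, pixel_count: float) -> np.ndarray:
    """Divide per-bin counts by the total pixel count to get probabilities."""
    counts = np.asarray(counts, dtype=np.float64)
    if pixel_count <= 0:
        raise ValueError(f"pixel_count must be positive, got {pixel_count}")
    total = float(counts.sum())
    if not np.isclose(total, pixel_count, rtol=1e-6, atol=1e-6):
        raise ValueError(
            f"pixel_count {pixel_count} does not match histogram total {total}"
        )
    return counts / pixel_count


def equalization_transfer(probs: np.ndarray, levels: int | None = None) -> np.ndarray:
    """Cumulative-histogram equalization lookup table.

    ``lut[k] = round((L - 1) * sum_{j <= k} probs[j])``, rounded half away
    from zero and clamped to ``[0, L-1]``. The result is non-decreasing in
    ``k`` because the cumulative sum is.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if levels is None:
        levels = probs.size
    raw = (levels - 1) * np.cumsum(probs)
    lut = np.clip(round_half_away(raw), 0, levels - 1).astype(np.int64)
    return lut


def apply_global_he(img: GrayImage) -> GrayImage:
    """Global histogram equalization (the whole-image baseline)."""
    counts = compute_histogram(img)
    probs = normalize_histogram(counts, img.n_pixels)
    lut = equalization_transfer(probs, img.levels)
    return GrayImage(lut[img.pixels], levels=img.levels)


def shannon_entropy(probs: np.ndarray) -> float:
    """Shannon entropy in bits of a normalized histogram; 0 <= H <= log2(bins)."""
    p = np.asarray(probs, dtype=np.float64)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log2(p)).sum())
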