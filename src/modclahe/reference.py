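"""Naive per-pixel reference implementation of the adaptive enhancement.

For every pixel this recomputes the four neighboring tiles' transfer
chains from scratch — histogram, variance-guided clip limit, clipping,
entropy-weighted redistribution, cumulative equalization — and blends the
four mapped values scalar-wise. Nothing tile-local is cached or shared
between pixels; only ``sigma_max`` (a whole-image scalar input of the clip
rule) is computed once up front. It exists purely as a validation oracle:
the optimized :func:`modclahe.clahe.apply_modified_clahe` must agree with
it bit-exactly. Deliberately wasteful; use only on small images.
"""

from __future__ import annotations

import math

import numpy as np

from .clahe import ClaheParams, hist_variance, make_tile_grid
from .image import GrayImage

__all__ = ["apply_modified_clahe_reference"]


def _mapped_value_from_scratch(
    padded: np.ndarray,
    tile_h: int,
    tile_w: int,
    params: ClaheParams,
    i: int,
    j: int,
    sigma_max: float,
    levels: int,
    v: int,
) -> float:
    """Recompute tile (i, j)'s transfer function and evaluate it at bin v."""
    tile = padded[i * tile_h : (i + 1) * tile_h, j * tile_w : (j + 1) * tile_w]
    counts = np.bincount(tile.reshape(-1), minlength=levels).astype(np.float64)
    if params.cl_is_base:
        sigma_hist = hist_variance(counts)
        ratio = 0.0 if sigma_max == 0 else sigma_hist / sigma_max
        if params.clip_mode == "multiplicative":
            cl_eff = params.cl * (1.0 + params.alpha * ratio)
        else:
            cl_eff = params.cl + params.alpha * ratio
        cl_eff = min(cl_eff, 1.0)
    else:
        cl_eff = params.cl
    h_count_max = counts.max()
    total = float(np.add.reduce(counts))
    h_count_mean = total / levels
    ceiling = h_count_max - cl_eff * (h_count_max - h_count_mean)
    clipped = np.minimum(counts, ceiling)
    excess = float(np.add.reduce(counts - clipped))
    if excess > 0:
        p = counts / total
        p = p[p > 0]
        h_tile = float(-np.add.reduce(p * np.log2(p)))
        n_bins = params.n_bins if params.n_bins is not None else levels
        h_max = math.log2(n_bins)
        weight = 0.0 if h_max == 0 else params.beta * (h_tile / h_max)
        clipped = clipped + weight * excess / n_bins
        clipped = clipped + (1.0 - weight) * excess / n_bins
    probs = clipped / total
    raw = (levels - 1) * np.cumsum(probs)[v]
    return min(max(math.floor(raw + 0.5), 0), levels - 1)


def apply_modified_clahe_reference(img: GrayImage, params: ClaheParams) -> GrayImage:
    """Per-pixel re-derivation of the enhanced image (the blending oracle)."""
    padded_img, grid = make_tile_grid(img, params.nt)
    padded = padded_img.pixels.astype(np.int64)
    levels = img.levels
    nt, th, tw = grid.nt, grid.tile_height, grid.tile_width

    sigma_max = 0.0
    for i in range(nt):
        for j in range(nt):
            tile = padded[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            counts = np.bincount(tile.reshape(-1), minlength=levels).astype(np.float64)
            sigma_max = max(sigma_max, hist_variance(counts))

    m, n = padded.shape
    out = np.zeros((m, n), dtype=np.int64)
    nt_hi = max(nt - 2, 0)
    for r in range(m):
        gr = min(max((r - (th - 1) / 2.0) / th, 0.0), nt - 1.0)
        i0 = min(int(math.floor(gr)), nt_hi)
        i1 = min(i0 + 1, nt - 1)
        fr = gr - i0
        for c in range(n):
            gc = min(max((c - (tw - 1) / 2.0) / tw, 0.0), nt - 1.0)
            j0 = min(int(math.floor(gc)), nt_hi)
            j1 = min(j0 + 1, nt - 1)
            fc = gc - j0
            v = int(padded[r, c])
            l00 = _mapped_value_from_scratch(padded, th, tw, params, i0, j0, sigma_max, levels, v)
            l01 = _mapped_value_from_scratch(padded, th, tw, params, i0, j1, sigma_max, levels, v)
            l10 = _mapped_value_from_scratch(padded, th, tw, params, i1, j0, sigma_max, levels, v)
            l11 = _mapped_value_from_scratch(padded, th, tw, params, i1, j1, sigma_max, levels, v)
            top = (1.0 - fc) * l00 + fc * l01
            bot = (1.0 - fc) * l10 + fc * l11
            val = (1.0 - fr) * top + fr * bot
            out[r, c] = min(max(int(math.floor(val + 0.5)), 0), levels - 1)
    if grid.needs_padding:
        out = out[: grid.orig_height, : grid.orig_width]
    return GrayImage(out, levels=levels)
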