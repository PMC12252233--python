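"""Seeded chest-radiograph-like phantoms and acquisition degradations.

The phantoms are deliberately schematic: a bright soft-tissue background,
two darker elliptical lung fields, periodic horizontal rib bands inside the
lungs, an optional brighter disk-shaped opacity (the "pneumonia" class) and
additive Gaussian read noise. Only the statistical structure matters — low
contrast, noise, and a localized class-discriminating opacity — so that
enhancement, quality scoring, parameter search and the classifier are all
exercisable offline with known ground truth.

Degradations emulate acquisition variability: a multiplicative intensity
reduction of 20-40% (low-dose imaging) and a contrast change of +/-15%
about the image mean (machine-to-machine variation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .image import GrayImage, round_half_away, write_image
from .quality import RegionSpec

__all__ = [
    "OpacitySpec",
    "PhantomSpec",
    "DegradationSpec",
    "generate_phantom",
    "degrade_intensity",
    "degrade_contrast",
    "generate_labeled_dataset",
    "save_dataset",
]


@dataclass(frozen=True)
class OpacitySpec:
    """A disk-shaped lesion: absolute center (row, col), radius and added intensity."""

    center: tuple[float, float]
    radius: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"opacity radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class PhantomSpec:
    """Generator parameters for one phantom.

    Defaults describe a low-contrast, moderately noisy 8-bit radiograph:
    soft tissue around intensity 170, lung fields 55 levels darker, rib
    bands of +/-10 levels, Gaussian read noise with sigma 8.
    """

    size: tuple[int, int] = (224, 224)
    background_level: float = 170.0
    lung_contrast: float = 55.0
    rib_amplitude: float = 10.0
    opacity: OpacitySpec | None = None
    noise_sigma: float = 8.0
    levels: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        m, n = self.size
        if m < 8 or n < 8:
            raise ValueError(f"phantom size {self.size} is degenerately small")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.opacity is not None:
            r, c = self.opacity.center
            if not (0 <= r < m and 0 <= c < n):
                raise ValueError("opacity center lies outside the image")


def _lung_masks(m: int, n: int) -> tuple[np.ndarray, np.ndarray, tuple, tuple]:
    """Two elliptical lung fields; returns masks and their centers/axes."""
    rr, cc = np.mgrid[0:m, 0:n].astype(np.float64)
    centers = ((0.52 * m, 0.30 * n), (0.52 * m, 0.70 * n))
    axes = (0.30 * m, 0.16 * n)
    masks = []
    for cr, ccol in centers:
        masks.append(((rr - cr) / axes[0]) ** 2 + ((cc - ccol) / axes[1]) ** 2 <= 1.0)
    return masks[0], masks[1], centers, axes


def _default_opacity(m: int, n: int) -> OpacitySpec:
    # centered in the left lung field, radius ~7% of the image height
    return OpacitySpec(center=(0.52 * m, 0.30 * n), radius=max(3.0, 0.07 * m), amplitude=40.0)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, RegionSpec, int]:
    """Render one phantom; deterministic for a fixed spec (incl. seed).

    Returns the image, a ground-truth :class:`RegionSpec` (opacity ROI vs a
    matched lung-background patch, or two lung-field patches when no
    opacity is present), and label 1 iff an opacity is present.
    """
    m, n = spec.size
    rng = np.random.default_rng(spec.seed)
    left, right, centers, axes = _lung_masks(m, n)
    canvas = np.full((m, n), spec.background_level, dtype=np.float64)
    lungs = left | right
    canvas[lungs] -= spec.lung_contrast
    period = max(8, m // 8)
    ribs = spec.rib_amplitude * np.sin(2 * np.pi * np.arange(m) / period)
    canvas[lungs] += np.broadcast_to(ribs[:, None], (m, n))[lungs]
    if spec.opacity is not None:
        rr, cc = np.mgrid[0:m, 0:n].astype(np.float64)
        cr, ccol = spec.opacity.center
        disk = (rr - cr) ** 2 + (cc - ccol) ** 2 <= spec.opacity.radius**2
        canvas[disk] += spec.opacity.amplitude
    if spec.noise_sigma > 0:
        canvas += rng.normal(0.0, spec.noise_sigma, size=(m, n))
    pixels = np.clip(round_half_away(canvas), 0, spec.levels - 1).astype(np.int64)
    img = GrayImage(pixels, levels=spec.levels)

    patch = max(4, int(round(0.08 * m)))
    if spec.opacity is not None:
        cr, ccol = spec.opacity.center
        side = max(2, int(spec.opacity.radius))  # inscribed-ish square
        roi = (int(cr - side / 2), int(ccol - side / 2), side, side)
        # local-surround background: same columns, just below the lesion disk
        # (lesion conspicuity is measured against its own lung field);
        # falls back to above the lesion, then to the other lung, when the
        # geometry is too cramped
        bg_col = int(ccol - side / 2)
        bg_row = int(cr + spec.opacity.radius + 3)
        if bg_row + side > m:
            bg_row = int(cr - spec.opacity.radius - 3 - side)
        if bg_row < 0:
            other = centers[1] if ccol < n / 2 else centers[0]
            bg_row = int(other[0] - side / 2)
            bg_col = int(other[1] - side / 2)
        bg = (bg_row, bg_col, side, side)
        regions = RegionSpec(roi=roi, background=bg)
        label = 1
    else:
        l, r = centers
        roi = (int(l[0] - patch / 2), int(l[1] - patch / 2), patch, patch)
        bg = (int(r[0] - patch / 2), int(r[1] - patch / 2), patch, patch)
        regions = RegionSpec(roi=roi, background=bg)
        label = 0
    regions.validate_within(img)
    return img, regions, label


def degrade_intensity(img: GrayImage, reduction: float) -> GrayImage:
    """Low-dose degradation: scale every pixel by ``1 - reduction``."""
    if not 0.0 <= reduction < 1.0:
        raise ValueError(f"reduction must lie in [0, 1), got {reduction}")
    out = round_half_away(img.astype_float() * (1.0 - reduction))
    return GrayImage(np.clip(out, 0, img.levels - 1).astype(np.int64), levels=img.levels)


def degrade_contrast(img: GrayImage, delta: float) -> GrayImage:
    """Contrast degradation: scale deviations from the image mean by ``1 + delta``."""
    if delta <= -1.0:
        raise ValueError(f"delta must be > -1, got {delta}")
    p = img.astype_float()
    mean = p.mean()
    out = round_half_away(mean + (p - mean) * (1.0 + delta))
    return GrayImage(np.clip(out, 0, img.levels - 1).astype(np.int64), levels=img.levels)


@dataclass(frozen=True)
class DegradationSpec:
    """Acquisition-variability ranges: 20-40% intensity loss, +/-15% contrast."""

    intensity_reduction: tuple[float, float] = (0.20, 0.40)
    contrast_delta: tuple[float, float] = (-0.15, 0.15)

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        lo, hi = self.intensity_reduction
        red = float(rng.uniform(lo, hi))
        lo, hi = self.contrast_delta
        delta = float(rng.uniform(lo, hi))
        return red, delta


def generate_labeled_dataset(
    n_per_class: int,
    base_spec: PhantomSpec | None = None,
    seed: int = 0,
    with_regions: bool = False,
) -> list[tuple]:
    """Balanced two-class phantom set with per-image jittered geometry.

    Per-image seeds derive deterministically from the master ``seed``; the
    opacity position, radius and amplitude, lung contrast and rib amplitude
    are all jittered so the classes are not trivially pixel-identical.
    Returns ``[(image, label), ...]`` (plus the region spec per item when
    ``with_regions``), alternating normal/opacity.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    base = base_spec if base_spec is not None else PhantomSpec()
    m, n = base.size
    master = np.random.SeedSequence(seed)
    children = master.spawn(2 * n_per_class)
    out = []
    for idx, child in enumerate(children):
        label = idx % 2
        rng = np.random.default_rng(child)
        img_seed = int(rng.integers(0, 2**31 - 1))
        jitter = dict(
            lung_contrast=base.lung_contrast * rng.uniform(0.85, 1.15),
            rib_amplitude=base.rib_amplitude * rng.uniform(0.8, 1.2),
        )
        if label == 1:
            proto = base.opacity if base.opacity is not None else _default_opacity(m, n)
            lung = (0.52 * m, 0.30 * n) if rng.uniform() < 0.5 else (0.52 * m, 0.70 * n)
            center = (
                lung[0] + rng.uniform(-0.10, 0.10) * m,
                lung[1] + rng.uniform(-0.05, 0.05) * n,
            )
            opacity = OpacitySpec(
                center=center,
                radius=proto.radius * rng.uniform(0.8, 1.2),
                amplitude=proto.amplitude * rng.uniform(0.8, 1.2),
            )
        else:
            opacity = None
        spec = replace(base, opacity=opacity, seed=img_seed, **jitter)
        img, regions, got_label = generate_phantom(spec)
        assert got_label == label
        out.append((img, label, regions) if with_regions else (img, label))
    return out


def save_dataset(
    dataset: list[tuple], out_dir: str | Path, prefix: str = "phantom"
) -> tuple[Path, Path]:
    """Write a generated dataset as PNGs plus labels.csv (and regions.csv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    label_rows, region_rows = [], []
    for i, item in enumerate(dataset):
        img, label = item[0], item[1]
        name = f"{prefix}_{i:04d}.png"
        write_image(img, out_dir / name)
        label_rows.append({"filename": name, "label": label})
        if len(item) > 2:
            regions: RegionSpec = item[2]
            region_rows.append(
                {
                    "filename": name,
                    "roi_row": regions.roi[0],
                    "roi_col": regions.roi[1],
                    "roi_height": regions.roi[2],
                    "roi_width": regions.roi[3],
                    "bg_row": regions.background[0],
                    "bg_col": regions.background[1],
                    "bg_height": regions.background[2],
                    "bg_width": regions.background[3],
                }
            )
    labels_path = out_dir / "labels.csv"
    pd.DataFrame(label_rows).to_csv(labels_path, index=False)
    regions_path = out_dir / "regions.csv"
    if region_rows:
        pd.DataFrame(region_rows).to_csv(regions_path, index=False)
    return labels_path, regions_path
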