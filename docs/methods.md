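# Methods

This note records the model, the numerical choices, and the open design
decisions behind `modclahe`, in the order the pipeline runs.

## Image model and histogram primitives

Images are 2-D integer rasters with an explicit level count `L` (default
256). `L` is a parameter everywhere so that 4-level toy images are exactly
testable. Coordinates are row-major and 0-based with pixel centers at
integer coordinates; bilinear resampling uses the align-corners
convention. Intensities produced by any stage are rounded half away from
zero and clamped to `[0, L-1]` — the rounding rule is a package
convention, chosen once and applied uniformly (equalization outputs,
blending, resampling, degradations, phantom rendering).

RGB inputs are collapsed by the unweighted channel mean; the target data
are nominally grayscale radiographs, so channel weighting is irrelevant.
Output images are always PNG to avoid recompression loss.

Histogram counts are carried as float vectors because clipping and
redistribution produce fractional mass. The equalization transfer is
`lut[k] = round((L-1) · cumsum(p)[k])`; it is non-decreasing by
construction since the cumulative sum is.

## The adaptive enhancement

Tiling uses `ceil` tile dimensions with bottom/right reflection padding
(numpy `symmetric` mode, edge-inclusive) and crops back after blending.
`nt` larger than the smallest image dimension is rejected (tiles would be
empty).

Clip semantics are inverted relative to most CLAHE implementations: the
per-bin ceiling is `c = h_max − CL·(h_max − h_mean)`, so `CL = 0` means no
clipping (plain per-tile equalization) and `CL = 1` caps at the mean bin
count. This realizes both stated endpoint behaviors exactly and is the
convention used throughout, including the search grid.

The variance modulation `CL_eff = CL_base·(1 + α·σ_hist/σ_max)` uses the
population variance of the 256-entry counts vector; `σ_max` is the
maximum over the tiles of the *current image*, and a zero `σ_max` defines
the ratio as 0. A grid-searched CL value is fed into this formula as
`CL_base` — the search and the modulation would otherwise both claim to
set the same quantity. An additive modulation form
(`CL_base + α·σ/σ_max`) exists behind `clip_mode="additive"` but is not
the default.

Redistribution is single-pass: bins may exceed the ceiling after mass
returns, and no re-clip iteration is performed. Because the tile entropy
is a per-tile scalar, the entropy-weighted share `β·(H_tile/H_max)·
excess/n_bins` plus the uniform remainder sum to exactly `excess/n_bins`
per bin; the two terms are kept explicit in the code because the weight
is the method's stated mechanism, and mass conservation is exact by
construction (verified to ~1e-16 relative in the acceptance sweep).

Blending interpolates at the mapping level: each pixel's output is the
bilinear combination of the four surrounding tile-center lookups
evaluated at the pixel's input value, with weights clamped at the image
border (edge pixels use two mappings, corners one). Tile centers sit at
`(r0 + (th−1)/2, c0 + (tw−1)/2)`.

A deliberately naive reference implementation re-derives every pixel from
scratch (recomputing the four neighboring tiles' transfer chains per
pixel, no caching) and must agree bit-exactly with the optimized path;
both sides share only one low-level primitive, the pairwise-reduction
histogram variance, so that the clip limits agree to the last bit.
With `nt=1, cl=0` the pipeline reduces exactly to global histogram
equalization, which serves as a second, independent oracle.

## Quality scoring

Scoring backends are a registry of `name -> callable(image) -> float`
with lower = better. BRISQUE-style scorers depend on a pretrained
natural-scene-statistics model, so they are attachable at runtime rather
than shipped; the default `surrogate` backend is deterministic:

    S = (1 − H_img/log2 L) + λ · NV/(L−1)²,   λ = 1, window = 7

`H_img` is global histogram entropy and `NV` the homogeneous-region noise
variance: the mean local variance over fully-contained `window×window`
sliding windows whose mean gradient magnitude lies in the lowest
quartile. Two measured properties of this estimator matter for
interpreting results:

* On pure iid Gaussian noise the quartile selection is negatively biased
  (gradient magnitude and local variance are correlated); at σ=10 on
  128×128 images it reads ≈78 rather than ≈98. It remains monotone in the
  noise amplitude, which is what the pipeline relies on.
* With λ=1 the noise term is numerically small next to the entropy term
  (NV/(L−1)² ≈ 0.01 for heavily amplified noise, versus entropy-term
  movements of ~0.1–0.5), so a grid search driven by the default
  surrogate favors maximal equalization (CL near 0). Raising λ shifts
  the optimum toward stronger clipping; λ is exposed for exactly that
  reason.

CNR is `|mean(roi) − mean(background)| / std(background)` over
caller-specified rectangles; the phantom generator emits ground-truth
regions, with the background patch in the same lung directly below the
lesion — the physically standard local-surround measurement of lesion
conspicuity, and stable under tile-local remapping (a mirrored-lung
background would compare values produced by different tile mappings).

## Parameter search and dataset pipeline

The search enumerates the full Cartesian grid (`NT` 2..24 step 2, `CL`
0..1 step 0.01; 1212 pairs) in NT-major ascending order, enhances and
scores every candidate, and takes the first minimum — which implements
the smallest-`nt`-then-smallest-`cl` tie-break for free. Infeasible `nt`
values are skipped with a warning. The dataset consensus is the modal
per-image optimum with the same tie-break. `ParamGrid.coarse()` (3 × 5
pairs) bounds search cost in smoke-scale runs; search can also be
restricted to a subset of images before the consensus is applied to all.

The dataset enhancer applies a quality gate: the enhanced image is written
only when its score is *strictly* lower than the original's, otherwise the
original is copied; "significant improvement" has no statistical
definition here, so strict improvement is the implemented meaning. The
manifest has one row per readable input regardless of the gate decision.

## Phantom generator

Phantoms are deliberately schematic chest-radiograph stand-ins: a bright
soft-tissue background (default level 170), two darker elliptical lung
fields (contrast 55), sinusoidal horizontal rib bands inside the lungs
(amplitude 10, period `max(8, rows/8)`), an optional hard-disk opacity,
and additive Gaussian read noise (σ=8). Poisson shot noise and anatomical
realism are deliberately omitted: the tests need the *statistical*
structure (low contrast, noise, a localized class-discriminating lesion)
plus closed-form ground truth, not realism. Consequences for
interpretation: passing tests demonstrate the mechanics and directional
behavior of the method, not clinical performance on real radiographs.

Labeled datasets alternate classes, derive per-image seeds from a master
seed via `SeedSequence.spawn`, and jitter lung contrast (±15%), rib
amplitude (±20%), and the lesion's lung, position, radius and amplitude
(±20%) so classes are not pixel-trivial. Degradations follow the
acquisition-variability model: intensity scaling by 20–40% (low dose) and
contrast scaling of deviations about the mean by ±15%, both pointwise,
rounded and clamped.

The "low-contrast noisy" study condition used by the quality-effect
checks is a 128×128 phantom with lung contrast 25, rib amplitude 6,
lesion amplitude 18 (radius 9), and noise σ=6 — contrast roughly halved
and lesion weakened relative to the defaults so that enhancement has
genuine headroom.

## Directional quality claims and the operating point

The claims "the adaptive enhancement raises lesion CNR versus the input"
and "keeps homogeneous-region noise at or below global HE's" are
evaluated at `nt=2, cl=0.5`: the coarsest tile count that the per-image
search typically selects, and the midpoint of the CL range, where the
contrast limit is genuinely active. The choice matters: with CL near 0
the "contrast-limited" method degenerates into per-tile equalization,
which amplifies homogeneous noise *more* than global HE (smaller tiles
stretch a pure-noise histogram across the full range), and the default
surrogate's search lands in that regime (see above). In the
contrast-limited band (`cl` roughly 0.4–0.6 at `nt=2`) both directional
effects hold in 50/50 seeded phantoms, and that is the regime the method
is designed for. The acceptance checks assert rates (≥90% of seeds), not
magnitudes.

## Classifier

The architecture is fixed apart from the input side length (multiple of
8, so three 2×2 poolings stay exact; default 224, smoke runs use 64):
conv-32/ReLU/pool, conv-64/BN/ReLU/pool, conv-128/BN/ReLU/pool, flatten,
dense-128/ReLU, dropout, dense-2 softmax. The first block has no batch
norm. The dropout rate defaults to 0.5 and is configurable (0.3 is the
documented alternative). Class 1 is the positive (opacity) class
throughout the metrics.

Training is plain Adam (lr 1e-3, β=0.9/0.999, batch 32, max 50 epochs)
with early stopping on validation loss (patience 10, strict improvement,
best weights restored). Two numerical safeguards are baked in: the
classifier head initializes with near-zero weights and gradients are
clipped to global norm 1.0 — without them, small-batch float32 training
intermittently blows up the initial logits and collapses the ReLU trunk
into a constant predictor. Batch norm keeps running statistics with
momentum 0.9 for inference. Training is bit-reproducible for a fixed
seed; inference disables dropout and is deterministic.

Undefined metric ratios (zero denominators) are reported as `None` with a
warning, never coerced to 0. ROC-AUC is the tie-averaged rank statistic
(Mann–Whitney), validated against exhaustive pairwise counting. K-fold
splitting delegates to scikit-learn's shuffled `KFold` (deterministic per
seed, larger folds first); per-fold metrics are summarized as mean ±
sample standard deviation.

## Problem sizes

The verification suite uses 64×64 phantoms for bit-identity checks
against the per-pixel reference (120 image/parameter combinations),
128×128 phantoms for the 50-seed quality-effect rates, ≥1000 randomized
tiles for conservation/monotonicity, exhaustive enumeration for the
4-bin/≤8-pixel clip endpoints, all confusion tables with counts ≤5, and
all length-≤6 tied score vectors for AUC. The end-to-end run trains on
250 phantoms at 64×64 with a coarse-grid consensus search on 10 of them.
These sizes were chosen so the full verification completes in a few
minutes while every check still runs at full strength.

## Known limitations

* The surrogate is not BRISQUE; absolute score levels are not comparable
  to published BRISQUE numbers, and search optima under the default λ
  favor weak clipping (documented above).
* The homogeneous-region noise estimator is biased low on pure noise.
* Phantoms are schematic; no claim transfers to real radiographs without
  re-evaluation on real data with a real quality backend.
* Color images are reduced to grayscale; DICOM and bit depths other than
  a single `L` per run are out of scope.
* The reference implementation is quadratic-ish in work and intended for
  small validation images only.
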