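# Methods

## Counting model

`nucleocount` counts DAPI-stained nuclei under three assumptions that
fluorescent nucleic staining of migrated cells satisfies well: low
variability of foreground gray levels, low variability of background
gray levels, and high contrast between the two. Under these conditions
a single global threshold separates nuclei from background, and all
remaining difficulty lies in objects that are not exactly one nucleus —
fused pairs, debris, partially migrated cells. The pipeline is:

1. intensity scaling to [0, 1] (integer sources divided by 2^depth − 1;
   RGB collapsed with luma weights 0.2989/0.5870/0.1140 normalized to
   sum to 1, so saturated white maps to exactly 1.0);
2. Otsu thresholding on a 256-bin histogram over [0, 1] (16-bit input
   is binned, not truncated); the chosen level is the left edge of the
   lowest bin maximizing the between-class variance ω₀ω₁(μ₀ − μ₁)²;
3. strict-greater binarization (pixels exactly at the level are
   background);
4. 8-connected component labeling, ordered left-to-right by centroid
   column (ties by row), with pixel-count areas;
5. representative nucleus area Ā = trimmed mean of areas at
   trim_percent p (default 10): k = floor(n·p/200) values dropped from
   each end of the sorted array — for n = 100, p = 10 that is exactly
   5 per tail; for small n it degrades to the plain mean;
6. total count Σ round_half_away(Aᵢ/Ā). Half-away rounding is load
   bearing: a ratio of exactly 1.5 must count as 2, which banker's
   rounding (the default of most numeric runtimes) would miscount.

Counts depend only on area *ratios*, which makes them invariant to
objective magnification and to nucleus shape. Border-touching objects
are included; excluding them would bias counts low. There is no
minimum-size prefilter: debris rejection is performed entirely by the
ratio < 0.5 discard.

### Degenerate inputs

* Constant (or single-histogram-bin) image: no histogram split has two
  non-empty classes. The threshold returned is the image's maximum
  intensity, so the foreground is empty and the count is 0. A plain
  argmax would return bin 0 and its left edge generally sits *below*
  the constant, which would turn the whole image into foreground.
* Zero-object image: the count is 0 with a logged warning, never an
  error — a blank field must not abort a batch run. The representative
  area is reported as absent.
* The slope p-value of a perfect regression fit underflows to 0; it is
  reported as computed rather than clamped.

## Synthetic scenes

The generator emulates membrane fields of view: flat-top disk (or
mildly elliptical, eccentricity ≤ 1.3) nuclei at intensity 0.85 on a
background of level 0.08 with additive Gaussian noise (sd 0.02, clipped
to [0, 1]). Mean nucleus areas follow the magnification presets
20.9 px² (2.5×), 62.4 px² (5×) and 256.1 px² (10×). The defaults obey
the contrast guarantee background + 3·noise_sd < nucleus_intensity,
which every `SceneSpec` re-validates on construction.

Design choices that make the ground truth authoritative:

* **Area sampling.** Singlet areas are log-normal around the preset
  mean (CV 0.10) truncated by resampling to [0.80, 1.20] × mean.
  Truncation keeps every singlet inside the [0.5, 1.5) one-cell
  rounding band with margin even when debris (which drags the trimmed
  mean down ~10%) or doublets (which push it up ~15%) shift the
  denominator: an unbounded log-normal occasionally produces a
  "singlet" above 1.5 × mean that the ratio rule would *correctly*
  count as two, falsifying the truth label rather than the algorithm.
* **Doublets** are two overlapping disks with centers 0.8 × (r₁ + r₂)
  apart — always one 8-connected component — whose union area targets
  uniform [1.85, 2.00] × mean, safely inside the two-cell band
  [1.5, 2.5) for every scene composition exercised.
* **Debris** specks are disks of area uniform [0.10, 0.30] × mean,
  rendered at full nucleus intensity: they survive thresholding and are
  rejected only by the ratio rule, which is the behavior under test.
* **Area snapping.** Each object's rasterized footprint is the level
  set of the normalized ellipse distance whose pixel count equals the
  sampled target area. At 2.5× a nucleus spans only ~21 px², where free
  rasterization scatters areas with sd ≈ 1 px² — enough to cross a
  rounding boundary roughly once per 50 000 singlets. Snapping pins
  every truth area to its target at every magnification.
* **Placement** is rejection sampling with a minimum edge-to-edge gap
  (default 3 px) between object footprints, guaranteeing objects never
  fuse; an unsatisfiable request raises a placement error naming the
  constraint. Auto-sized canvases (`SceneSpec.for_preset`) keep the
  foreground fill fraction near 8% regardless of object count: with a
  vanishing foreground class, Otsu's criterion can otherwise be
  maximized by a split *inside* the background noise distribution.
* **Blank scenes** (no objects requested) are rendered without noise.
  A global threshold applied to pure noise splits the noise itself;
  with no nuclei there is no separability for the noise model to
  stress, and a truly blank field is the meaningful degenerate. This is
  also a real limitation of the method on object-free images.
* **Magnification series** sample one layout at the base scale and
  re-render it with positions and radii multiplied by
  √(preset mean / base mean), so the three scenes share one true count.

What the generator does **not** emulate: point-spread blur, uneven
illumination or vignetting, intensity variation within and between
nuclei, clusters of three or more fused nuclei, non-migrated cell
remnants, or montage seams. Passing tests therefore certify the
counting rules and their scale-invariance on well-separated,
high-contrast objects — the regime the method assumes — not robustness
to optical artifacts.

## Batch processing and validation

A TIFF series is processed in lexicographic (byte-order) filename
order, so sequential acquisition requires zero-padded numbering; the
ordering is internal and independent of directory-listing order.
Unreadable files are logged and recorded as error rows without aborting
the batch (only an all-failure batch errors). Reports are CSV with
columns `filename,threshold_level,n_objects,mean_nucleus_area,
total_count`; repeated runs over the same inputs are byte-identical.

The validation harness regresses automated on manual counts with
ordinary least squares: slope, intercept, r² = (Pearson r)², the
two-sided t-test of the slope against zero on n − 2 degrees of freedom
(for simple linear regression this coincides with the F-test), 95%
t-based confidence intervals, and the mean per-image difference.
Degenerate inputs (fewer than 3 pairs, zero x-variance, mismatched
filename sets) are rejected explicitly.

## Problem sizes in the test suite

Exact ground-truth recovery is exercised at N ∈ {1, 10, 50, 200, 500}
singlets per magnification preset with 20 seeds each; doublet/debris
semantics (20 singlets + 5 doublets + 10 debris → 30) over 20 seeds;
magnification invariance over 20 layouts of 30 singlets + 5 doublets;
batch determinism over a 47-image mixed series run twice through the
CLI; threshold selection against an exact-rational exhaustive scan on
200 random 64×64 images. The full suite runs in well under a minute on
one core.

## Known limitations

* A single global threshold presumes uniform illumination; shading
  across a montage would need correction upstream.
* Heavily overlapping clusters (three or more nuclei) are counted by
  area ratio alone; systematic multinucleation inflates the
  representative area and deflates counts, as the ratio mechanism
  assumes the *majority* of objects are single nuclei.
* On images containing only debris, the trimmed mean adapts to the
  debris areas themselves and counts them as cells; the ratio rule
  rejects debris only relative to a nucleus-dominated population.
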