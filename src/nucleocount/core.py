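"""Four-stage nucleus counting: threshold, binarize, label, ratio-count.

The counting model assumes DAPI-stained nuclei imaged as bright, roughly
circular blobs on a dark background with high foreground/background
contrast.  A single global Otsu threshold separates nuclei from
background, connected components give per-object pixel areas, a 10%
trimmed mean of those areas defines the representative single-nucleus
area, and each object contributes ``round(area / representative_area)``
cells.  The rounding rule is the mechanism that both discards debris
(ratio < 0.5 contributes 0) and splits fused doublets (ratio in
[1.5, 2.5) contributes 2) without any shape-based segmentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = [
    "GrayscaleImage",
    "BinaryMask",
    "ObjectTable",
    "CountResult",
    "NoObjectsError",
    "to_grayscale",
    "compute_otsu_threshold",
    "binarize",
    "label_objects",
    "trimmed_mean_area",
    "count_from_areas",
    "count_image",
    "N_HISTOGRAM_BINS",
]

logger = logging.getLogger(__name__)

#: Otsu histogram resolution, fixed regardless of source bit depth.
N_HISTOGRAM_BINS = 256

# Rec. 601 luma weights, normalized to sum exactly to 1 so a saturated
# white pixel still maps to 1.0 after channel collapse.
_LUMA_WEIGHTS = np.array([0.2989, 0.5870, 0.1140])
_LUMA_WEIGHTS = _LUMA_WEIGHTS / _LUMA_WEIGHTS.sum()

_SUPPORTED_BIT_DEPTHS = (8, 16)


class NoObjectsError(ValueError):
    """Raised when an operation requiring foreground objects gets none."""


@dataclass(frozen=True)
class GrayscaleImage:
    """A single-channel field of view with intensities scaled to [0, 1].

    ``source_bit_depth`` records the integer depth the pixel data came
    from; conversion is ``value / (2**depth - 1)`` so a saturated source
    pixel maps to exactly 1.0.
    """

    pixels: np.ndarray
    source_bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(
                f"GrayscaleImage requires a non-empty 2-D grid, got shape {px.shape}"
            )
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        if self.source_bit_depth not in _SUPPORTED_BIT_DEPTHS:
            raise ValueError(
                f"unsupported source bit depth {self.source_bit_depth}; expected 8 or 16"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class BinaryMask:
    """Foreground mask over {0, 1} with the dimensions of its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"BinaryMask requires a non-empty 2-D grid, got {px.shape}")
        if not np.isin(px, (0, 1)).all():
            raise ValueError("mask pixels must be exactly 0 or 1")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ObjectTable:
    """Connected components of a mask, labeled left-to-right.

    Labels run 1..N ordered by centroid column (ties by centroid row),
    mirroring sequential left-to-right object numbering on a membrane
    image.  ``label_map`` assigns each foreground pixel its object's
    label, 0 for background.
    """

    labels: np.ndarray          # int, 1..N
    centroid_rows: np.ndarray   # float
    centroid_cols: np.ndarray   # float
    areas: np.ndarray           # int, px^2
    label_map: np.ndarray       # int, same shape as source mask

    def __len__(self) -> int:
        return len(self.labels)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "label": self.labels,
                "centroid_row": self.centroid_rows,
                "centroid_col": self.centroid_cols,
                "area": self.areas,
            }
        )


@dataclass(frozen=True)
class CountResult:
    """Per-image output of the full counting pipeline."""

    image_id: str
    threshold_level: float
    n_objects: int
    mean_nucleus_area: float | None
    total_count: int
    trim_percent: float = 10.0
    error: str | None = None


def to_grayscale(image: np.ndarray, bit_depth: int | None = None) -> GrayscaleImage:
    """Convert a raw 1- or 3-channel integer pixel grid to a GrayscaleImage.

    Three-channel input is collapsed with fixed luma weights
    0.2989/0.5870/0.1140 before rescaling; one-channel input is only
    rescaled by ``2**depth - 1``.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if bit_depth is None:
        if arr.dtype == np.uint8:
            bit_depth = 8
        elif arr.dtype == np.uint16:
            bit_depth = 16
        else:
            raise ValueError(
                f"cannot infer bit depth from dtype {arr.dtype}; pass bit_depth=8 or 16"
            )
    if bit_depth not in _SUPPORTED_BIT_DEPTHS:
        raise ValueError(f"unsupported bit depth {bit_depth}; expected 8 or 16")

    if arr.ndim == 3:
        if arr.shape[2] != 3:
            raise ValueError(
                f"unsupported channel count {arr.shape[2]} for shape {arr.shape}; "
                "expected 1 or 3 channels"
            )
        arr = arr.astype(float) @ _LUMA_WEIGHTS
    elif arr.ndim != 2:
        raise ValueError(f"unsupported image shape {arr.shape}; expected 2-D or H x W x 3")

    scale = float(2**bit_depth - 1)
    # clip guards the [0, 1] invariant against ~1e-16 luma rounding
    return GrayscaleImage(
        pixels=np.clip(arr.astype(float) / scale, 0.0, 1.0), source_bit_depth=bit_depth
    )


def _histogram(img: GrayscaleImage) -> np.ndarray:
    hist, _ = np.histogram(img.pixels, bins=N_HISTOGRAM_BINS, range=(0.0, 1.0))
    return hist.astype(float)


def compute_otsu_threshold(img: GrayscaleImage) -> float:
    """Global Otsu threshold on a 256-bin histogram over [0, 1].

    Candidate thresholds are the left edges k/256 of each bin; the
    between-class variance w0*w1*(mu0 - mu1)^2 of the split
    {bins < k} vs {bins >= k} is maximized, ties resolved toward the
    lowest bin.  A constant image (single occupied bin) has no valid
    split; the image's maximum intensity is returned (for a constant
    image, the constant itself), which leaves the foreground empty under
    strict-greater binarization.
    """
    hist = _histogram(img)
    occupied = np.flatnonzero(hist)
    if occupied.size == 1:
        return float(img.pixels.max())

    p = hist / hist.sum()
    bin_idx = np.arange(N_HISTOGRAM_BINS)
    omega = np.cumsum(p)            # omega[k] = weight of bins 0..k
    mu = np.cumsum(p * bin_idx)     # mu[k]   = first moment of bins 0..k
    mu_total = mu[-1]

    # Split at threshold k/256 puts bins 0..k-1 in the background class.
    w0 = omega[:-1]
    m0 = mu[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_total * w0 - m0) ** 2 / (w0 * (1.0 - w0))
    sigma_b = np.where((w0 > 0) & (w0 < 1), sigma_b, -np.inf)

    k = int(np.argmax(sigma_b)) + 1  # argmax returns the lowest maximizer
    return k / N_HISTOGRAM_BINS


def binarize(img: GrayscaleImage, level: float) -> BinaryMask:
    """Threshold strictly above ``level``: pixel -> 1 iff intensity > level.

    Pixels exactly at the threshold go to background.
    """
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"threshold level {level} outside [0, 1]")
    return BinaryMask(pixels=(img.pixels > level).astype(np.uint8))


def label_objects(mask: BinaryMask) -> ObjectTable:
    """Label 8-connected components, ordered left-to-right by centroid.

    Areas are pixel counts; centroids are arithmetic-mean pixel
    positions.  An empty mask yields an empty table.
    """
    raw = measure.label(mask.pixels, connectivity=2)
    props = measure.regionprops(raw)
    if not props:
        empty = np.array([], dtype=int)
        return ObjectTable(
            labels=empty,
            centroid_rows=np.array([], dtype=float),
            centroid_cols=np.array([], dtype=float),
            areas=empty.copy(),
            label_map=np.zeros_like(raw),
        )

    rows = np.array([p.centroid[0] for p in props])
    cols = np.array([p.centroid[1] for p in props])
    areas = np.array([p.area for p in props], dtype=int)
    old_labels = np.array([p.label for p in props], dtype=int)

    order = np.lexsort((rows, cols))  # primary key: column, then row
    lut = np.zeros(raw.max() + 1, dtype=int)
    lut[old_labels[order]] = np.arange(1, len(order) + 1)

    return ObjectTable(
        labels=np.arange(1, len(order) + 1),
        centroid_rows=rows[order],
        centroid_cols=cols[order],
        areas=areas[order],
        label_map=lut[raw],
    )


def trimmed_mean_area(areas, trim_percent: float = 10.0) -> float:
    """Representative nucleus area: symmetric trimmed mean of object areas.

    With trim_percent p, k = floor(n * p / 200) values are dropped from
    each end of the sorted array (p/2 percent per tail), and the mean of
    the remainder is returned.  For small n where k = 0 this degrades to
    the plain mean.
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise NoObjectsError("no objects: cannot compute a representative nucleus area")
    if not 0.0 <= trim_percent < 100.0:
        raise ValueError(f"trim_percent {trim_percent} outside [0, 100)")
    n = areas.size
    k = int(np.floor(n * trim_percent / 200.0))
    trimmed = np.sort(areas)[k : n - k]
    return float(trimmed.mean())


def count_from_areas(areas, mean_area: float) -> int:
    """Sum of per-object cell counts round(area / mean_area).

    Rounding is half-away-from-zero, so a ratio of exactly 1.5 counts as
    2 cells; ratios below 0.5 contribute nothing (debris discard).
    """
    if mean_area <= 0:
        raise ValueError(f"mean_area must be positive, got {mean_area}")
    ratios = np.asarray(areas, dtype=float) / mean_area
    # positive ratios: half-away-from-zero == floor(x + 0.5)
    return int(np.floor(ratios + 0.5).sum())


def count_image(
    img: GrayscaleImage, trim_percent: float = 10.0, image_id: str = ""
) -> CountResult:
    """Run the full pipeline on one image and return its CountResult."""
    level = compute_otsu_threshold(img)
    mask = binarize(img, level)
    table = label_objects(mask)
    if len(table) == 0:
        logger.warning("image %r: no foreground objects, count is 0", image_id)
        return CountResult(
            image_id=image_id,
            threshold_level=level,
            n_objects=0,
            mean_nucleus_area=None,
            total_count=0,
            trim_percent=trim_percent,
        )
    mean_area = trimmed_mean_area(table.areas, trim_percent)
    total = count_from_areas(table.areas, mean_area)
    return CountResult(
        image_id=image_id,
        threshold_level=level,
        n_objects=len(table),
        mean_nucleus_area=mean_area,
        total_count=total,
        trim_percent=trim_percent,
    )
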