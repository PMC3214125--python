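"""Ground-truth synthetic DAPI scenes for exercising the counting pipeline.

Scenes emulate migration-assay membrane images: bright, roughly circular
nuclei at magnification-dependent mean areas (20.9 px^2 at 2.5x, 62.4 at
5x, 256.1 at 10x) on a dim, noisy background, optionally with fused
doublets (two overlapping disks forming one connected component of about
twice the singlet area) and sub-threshold-ratio debris specks.  Every
scene carries its ground truth, so recovered counts can be compared with
the number of cells actually placed.

Two generator choices keep the truth labels consistent with the
area-ratio counting semantics the scenes are meant to certify:

* Singlet areas follow a log-normal around the preset mean (CV 0.10 by
  default) truncated by resampling to [0.80, 1.20] x the mean, and
  doublet union areas target [1.85, 2.00] x the mean.  The counting rule
  by construction reads any object outside [0.5, 1.5) x the
  representative area as not-one-cell, so a "singlet" outside the
  single-cell rounding band would carry a wrong truth label rather than
  expose an algorithmic error.

* Each object's rasterized footprint is snapped to its sampled target
  area: the rendered pixel set is chosen by thresholding the normalized
  ellipse distance at the level whose pixel count matches the target.
  At 2.5x a nucleus spans only ~21 px^2, where free rasterization
  scatters areas by several px^2; snapping pins every truth area to its
  target within quantization, at every magnification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

from .core import GrayscaleImage

__all__ = [
    "MAGNIFICATION_PRESETS",
    "SceneSpec",
    "SyntheticScene",
    "PlacementError",
    "generate_scene",
    "make_magnification_series",
    "write_scene",
]

#: Mean single-nucleus areas (px^2) by objective magnification.
MAGNIFICATION_PRESETS: dict[str, float] = {"2.5x": 20.9, "5x": 62.4, "10x": 256.1}

# Singlet-area truncation band (fraction of the preset mean): keeps every
# singlet inside the [0.5, 1.5) single-cell rounding interval with margin,
# even when debris or doublets shift the trimmed mean by ~10-15%.
_AREA_BAND = (0.80, 1.20)
# Doublet union-area targets (fraction of the singlet mean).
_DOUBLET_UNION_BAND = (1.85, 2.00)
# Debris speck areas as a fraction of the singlet mean (< 0.4 per contract).
_DEBRIS_BAND = (0.10, 0.30)
# Doublet component centers sit at 0.8 x the sum of their radii.
_DOUBLET_SEPARATION = 0.8
# Footprint snapping may swell radii by up to this factor; placement
# reserves the extra extent so objects can never fuse.
_SNAP_FACTOR = 1.25

_MAX_PLACEMENT_TRIES = 500


class PlacementError(RuntimeError):
    """Requested objects cannot be placed at min_separation on the canvas."""


@dataclass(frozen=True)
class SceneSpec:
    """Declarative description of a synthetic membrane field of view.

    ``area_cv`` is the coefficient of variation of nucleus areas;
    ``min_separation`` is the minimum edge-to-edge gap (px) between
    distinct objects, guaranteeing they rasterize to separate
    8-connected components.
    """

    image_height: int
    image_width: int
    n_singlets: int = 0
    n_doublets: int = 0
    n_debris: int = 0
    mean_nucleus_area: float = MAGNIFICATION_PRESETS["2.5x"]
    area_cv: float = 0.10
    nucleus_intensity: float = 0.85
    background_level: float = 0.08
    noise_sd: float = 0.02
    min_separation: float = 3.0
    seed: int = 0
    max_eccentricity: float = 1.0

    def __post_init__(self) -> None:
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("canvas dimensions must be positive")
        if min(self.n_singlets, self.n_doublets, self.n_debris) < 0:
            raise ValueError("object counts must be non-negative")
        if self.mean_nucleus_area <= 0:
            raise ValueError("mean_nucleus_area must be positive")
        if not 0.0 < self.nucleus_intensity <= 1.0:
            raise ValueError("nucleus_intensity must lie in (0, 1]")
        if not 0.0 <= self.background_level < 1.0:
            raise ValueError("background_level must lie in [0, 1)")
        if self.background_level + 3.0 * self.noise_sd >= self.nucleus_intensity:
            raise ValueError(
                "contrast guarantee violated: background_level + 3*noise_sd "
                f"({self.background_level + 3 * self.noise_sd:.3f}) must stay below "
                f"nucleus_intensity ({self.nucleus_intensity:.3f})"
            )
        if not 1.0 <= self.max_eccentricity <= 1.3:
            raise ValueError("max_eccentricity must lie in [1.0, 1.3]")

    @classmethod
    def for_preset(
        cls,
        preset: str,
        n_singlets: int = 0,
        n_doublets: int = 0,
        n_debris: int = 0,
        seed: int = 0,
        fill_fraction: float = 0.08,
        **overrides,
    ) -> "SceneSpec":
        """Build a spec at a magnification preset with an auto-sized canvas.

        The canvas is sized so nuclei cover roughly ``fill_fraction`` of
        the pixels.  Keeping the fill fraction constant (rather than the
        canvas) matters for sparse fields: a global-threshold histogram
        with a vanishing foreground class can otherwise be split inside
        the background noise.
        """
        if preset not in MAGNIFICATION_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; expected one of {sorted(MAGNIFICATION_PRESETS)}"
            )
        mean = MAGNIFICATION_PRESETS[preset]
        total_area = mean * (
            n_singlets + _DOUBLET_UNION_BAND[1] * n_doublets + _DEBRIS_BAND[1] * n_debris
        )
        side = max(48, math.ceil(math.sqrt(total_area / fill_fraction)))
        return cls(
            image_height=side,
            image_width=side,
            n_singlets=n_singlets,
            n_doublets=n_doublets,
            n_debris=n_debris,
            mean_nucleus_area=mean,
            seed=seed,
            **overrides,
        )


@dataclass(frozen=True)
class _Disk:
    drow: float
    dcol: float
    radius: float
    eccentricity: float
    angle: float


@dataclass(frozen=True)
class _Site:
    kind: str              # "singlet" | "doublet" | "debris"
    row: float
    col: float
    disks: tuple[_Disk, ...]
    extent: float          # bounding radius around (row, col), snap-inflated
    target_area: float     # px^2 at base scale


@dataclass(frozen=True)
class SyntheticScene:
    """A rendered scene plus its ground truth."""

    image: GrayscaleImage
    truth: list[dict]      # per object: center, area (px^2), kind
    true_cell_count: int
    spec: SceneSpec


def _truncated_lognormal(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal areas with the stated mean and CV, resampled into _AREA_BAND."""
    if n == 0:
        return np.empty(0)
    if cv == 0.0:
        return np.full(n, mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    lo, hi = _AREA_BAND[0] * mean, _AREA_BAND[1] * mean
    out = rng.lognormal(mu, math.sqrt(sigma2), n)
    for _ in range(100):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.lognormal(mu, math.sqrt(sigma2), int(bad.sum()))
    return np.clip(out, lo, hi)


def _disk_shape(rng: np.random.Generator, spec: SceneSpec) -> tuple[float, float]:
    if spec.max_eccentricity == 1.0:
        return 1.0, 0.0
    return float(rng.uniform(1.0, spec.max_eccentricity)), float(rng.uniform(0, math.pi))


def _sample_sites(spec: SceneSpec, rng: np.random.Generator) -> list[_Site]:
    """Sample object shapes and targets, then place by rejection sampling."""
    sites: list[_Site] = []

    # Doublets first (largest footprints pack easiest early).
    for _ in range(spec.n_doublets):
        a1, a2 = _truncated_lognormal(rng, spec.mean_nucleus_area, spec.area_cv, 2)
        r1, r2 = math.sqrt(a1 / math.pi), math.sqrt(a2 / math.pi)
        d = _DOUBLET_SEPARATION * (r1 + r2)
        theta = rng.uniform(0, 2 * math.pi)
        dr, dc = (d / 2) * math.sin(theta), (d / 2) * math.cos(theta)
        e1, t1 = _disk_shape(rng, spec)
        e2, t2 = _disk_shape(rng, spec)
        disks = (
            _Disk(dr, dc, r1, e1, t1),
            _Disk(-dr, -dc, r2, e2, t2),
        )
        extent = _SNAP_FACTOR * max(
            d / 2 + r1 * math.sqrt(e1), d / 2 + r2 * math.sqrt(e2)
        )
        union_target = spec.mean_nucleus_area * rng.uniform(*_DOUBLET_UNION_BAND)
        sites.append(_Site("doublet", 0.0, 0.0, disks, extent, union_target))

    for area in _truncated_lognormal(rng, spec.mean_nucleus_area, spec.area_cv, spec.n_singlets):
        r = math.sqrt(area / math.pi)
        e, t = _disk_shape(rng, spec)
        sites.append(
            _Site(
                "singlet",
                0.0,
                0.0,
                (_Disk(0.0, 0.0, r, e, t),),
                _SNAP_FACTOR * r * math.sqrt(e),
                float(area),
            )
        )

    if spec.n_debris:
        debris_areas = spec.mean_nucleus_area * rng.uniform(
            _DEBRIS_BAND[0], _DEBRIS_BAND[1], spec.n_debris
        )
        for area in debris_areas:
            r = max(math.sqrt(area / math.pi), 0.6)
            sites.append(
                _Site(
                    "debris", 0.0, 0.0, (_Disk(0.0, 0.0, r, 1.0, 0.0),),
                    _SNAP_FACTOR * r, float(area),
                )
            )

    # Rejection-sample positions with pairwise edge gaps >= min_separation.
    placed_r = np.empty(len(sites))
    placed_c = np.empty(len(sites))
    placed_ext = np.empty(len(sites))
    out: list[_Site] = []
    for i, site in enumerate(sites):
        margin = site.extent + 1.0
        lo_r, hi_r = margin, spec.image_height - margin
        lo_c, hi_c = margin, spec.image_width - margin
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PlacementError(
                f"{site.kind} of extent {site.extent:.1f} px does not fit the "
                f"{spec.image_height}x{spec.image_width} canvas"
            )
        for _ in range(_MAX_PLACEMENT_TRIES):
            row = rng.uniform(lo_r, hi_r)
            col = rng.uniform(lo_c, hi_c)
            if i:
                dist = np.hypot(placed_r[:i] - row, placed_c[:i] - col)
                if (dist < placed_ext[:i] + site.extent + spec.min_separation).any():
                    continue
            break
        else:
            raise PlacementError(
                f"could not place object {i + 1}/{len(sites)} at "
                f"min_separation={spec.min_separation} px on a "
                f"{spec.image_height}x{spec.image_width} canvas; "
                "enlarge the canvas or reduce the object count"
            )
        placed_r[i], placed_c[i], placed_ext[i] = row, col, site.extent
        out.append(replace(site, row=row, col=col))
    return out


def _footprint(site: _Site, scale: float, shape: tuple[int, int]) -> np.ndarray:
    """Flat pixel indices of a site rendered at ``scale``, area-snapped.

    Pixels are ranked by their normalized ellipse distance q (minimum
    over the site's disks; q = 1 on the nominal outline), and the
    footprint is the q-threshold level set whose pixel count matches the
    scaled target area.  The threshold may move the outline by at most
    _SNAP_FACTOR in radius.
    """
    h, w = shape
    f2_max = _SNAP_FACTOR**2
    # Combined bounding box at maximal snap inflation.
    half = site.extent  # already snap-inflated
    cr, cc = site.row * scale, site.col * scale
    r0 = max(int(math.floor(cr - half * scale)) - 1, 0)
    r1 = min(int(math.ceil(cr + half * scale)) + 2, h)
    c0 = max(int(math.floor(cc - half * scale)) - 1, 0)
    c1 = min(int(math.ceil(cc + half * scale)) + 2, w)

    rows = np.arange(r0, r1, dtype=float)[:, None]
    cols = np.arange(c0, c1, dtype=float)[None, :]
    q = np.full((r1 - r0, c1 - c0), np.inf)
    for disk in site.disks:
        dcr = (site.row + disk.drow) * scale
        dcc = (site.col + disk.dcol) * scale
        a = disk.radius * scale * math.sqrt(disk.eccentricity)
        b = disk.radius * scale / math.sqrt(disk.eccentricity)
        ct, st = math.cos(disk.angle), math.sin(disk.angle)
        u = (rows - dcr) * ct + (cols - dcc) * st
        v = -(rows - dcr) * st + (cols - dcc) * ct
        np.minimum(q, (u / a) ** 2 + (v / b) ** 2, out=q)

    target = max(1, round(site.target_area * scale * scale))
    qflat = q.ravel()
    eligible = np.sort(qflat[qflat <= f2_max])
    if eligible.size == 0:
        # Degenerate sub-pixel object: claim the single nearest pixel.
        level = float(qflat.min())
    elif target >= eligible.size:
        level = float(eligible[-1])
    else:
        level = float(eligible[target - 1])
    inside = q <= level
    rr, cc_idx = np.nonzero(inside)
    return (rr + r0) * w + (cc_idx + c0)


def _render(
    sites: list[_Site],
    spec: SceneSpec,
    scale: float,
    shape: tuple[int, int],
    noise_rng: np.random.Generator,
) -> SyntheticScene:
    base = np.full(shape, spec.background_level)
    truth = []
    for site in sites:
        idx = _footprint(site, scale, shape)
        base.flat[idx] = spec.nucleus_intensity
        truth.append(
            {
                "center": [site.row * scale, site.col * scale],
                "area": int(idx.size),
                "kind": site.kind,
            }
        )
    # A scene with no objects is a truly blank field: the noise model
    # exists to stress nucleus/background separability, and with nothing
    # to separate, a global threshold on pure noise would only split the
    # noise itself.
    if spec.noise_sd > 0 and sites:
        base = base + noise_rng.normal(0.0, spec.noise_sd, shape)
    image = GrayscaleImage(pixels=np.clip(base, 0.0, 1.0))
    return SyntheticScene(
        image=image,
        truth=truth,
        true_cell_count=spec.n_singlets + 2 * spec.n_doublets,
        spec=spec,
    )


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene; a pure function of the spec (seed included)."""
    rng = np.random.default_rng(spec.seed)
    sites = _sample_sites(spec, rng)
    return _render(sites, spec, 1.0, (spec.image_height, spec.image_width), rng)


def make_magnification_series(base_spec: SceneSpec) -> dict[str, SyntheticScene]:
    """Render one cell layout at all three magnification presets.

    The layout is sampled once at ``base_spec``'s scale; for each preset
    all positions and radii are multiplied by sqrt(preset_mean /
    base_mean) and the canvas scales accordingly, so the three scenes
    share an identical true cell count.
    """
    rng = np.random.default_rng(base_spec.seed)
    sites = _sample_sites(base_spec, rng)
    series = {}
    for i, (preset, mean) in enumerate(MAGNIFICATION_PRESETS.items()):
        s = math.sqrt(mean / base_spec.mean_nucleus_area)
        shape = (
            max(1, round(base_spec.image_height * s)),
            max(1, round(base_spec.image_width * s)),
        )
        noise_rng = np.random.default_rng([base_spec.seed, i])
        scaled_spec = replace(
            base_spec,
            image_height=shape[0],
            image_width=shape[1],
            mean_nucleus_area=mean,
        )
        series[preset] = _render(sites, scaled_spec, s, shape, noise_rng)
    return series


def write_scene(scene: SyntheticScene, image_path, truth_path) -> None:
    """Save the image as 8-bit grayscale TIFF and the truth as JSON."""
    image_path, truth_path = Path(image_path), Path(truth_path)
    quantized = np.round(scene.image.pixels * 255.0).astype(np.uint8)
    try:
        tifffile.imwrite(image_path, quantized)
    except OSError as exc:
        raise OSError(f"failed to write TIFF {image_path}: {exc}") from exc
    payload = {
        "true_cell_count": scene.true_cell_count,
        "n_singlets": scene.spec.n_singlets,
        "n_doublets": scene.spec.n_doublets,
        "n_debris": scene.spec.n_debris,
        "objects": scene.truth,
    }
    try:
        truth_path.write_text(json.dumps(payload, indent=1))
    except OSError as exc:
        raise OSError(f"failed to write truth JSON {truth_path}: {exc}") from exc
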