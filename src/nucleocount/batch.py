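"""Batch counting of a TIFF series in sequential filename order."""

from __future__ import annotations

import fnmatch
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import CountResult, GrayscaleImage, count_image, to_grayscale

__all__ = [
    "RunConfig",
    "BatchReport",
    "read_image",
    "discover_series",
    "process_series",
    "write_report",
]

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["filename", "threshold_level", "n_objects", "mean_nucleus_area", "total_count"]


@dataclass(frozen=True)
class RunConfig:
    input_dir: Path
    output_path: Path | None = None
    pattern: str = "*.tif"
    trim_percent: float = 10.0
    log_level: str = "WARNING"

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_dir", Path(self.input_dir))
        if not 0.0 <= self.trim_percent < 100.0:
            raise ValueError(f"trim_percent {self.trim_percent} outside [0, 100)")
        if not self.input_dir.is_dir():
            raise NotADirectoryError(f"input directory does not exist: {self.input_dir}")


@dataclass(frozen=True)
class BatchReport:
    rows: list[CountResult]

    @property
    def n_images(self) -> int:
        return len(self.rows)

    @property
    def grand_total(self) -> int:
        return sum(r.total_count for r in self.rows if r.error is None)

    def to_dataframe(self) -> pd.DataFrame:
        records = []
        for r in self.rows:
            if r.error is None:
                records.append(
                    (r.image_id, r.threshold_level, r.n_objects, r.mean_nucleus_area, r.total_count)
                )
            else:
                records.append((r.image_id, np.nan, np.nan, np.nan, np.nan))
        return pd.DataFrame(records, columns=REPORT_COLUMNS)


def read_image(path) -> GrayscaleImage:
    """Read a grayscale (8/16-bit) or RGB (8-bit) TIFF field of view."""
    path = Path(path)
    try:
        raw = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise OSError(f"failed to read TIFF {path}: {exc}") from exc
    return to_grayscale(raw)


def discover_series(config: RunConfig) -> list[Path]:
    """Matching files sorted lexicographically by name (byte order).

    Sequential-filename ordering implies zero-padded numbering: img2.tif
    sorts after img10.tif.
    """
    names = sorted(
        p.name
        for p in config.input_dir.iterdir()
        if p.is_file() and fnmatch.fnmatchcase(p.name, config.pattern)
    )
    if not names:
        raise FileNotFoundError(
            f"no files matching {config.pattern!r} in {config.input_dir}"
        )
    return [config.input_dir / n for n in names]


def process_series(config: RunConfig) -> BatchReport:
    """Count every image in the series; unreadable files become error rows."""
    rows: list[CountResult] = []
    for path in discover_series(config):
        try:
            img = read_image(path)
            rows.append(count_image(img, trim_percent=config.trim_percent, image_id=path.name))
        except (OSError, ValueError) as exc:
            logger.error("skipping %s: %s", path.name, exc)
            rows.append(
                CountResult(
                    image_id=path.name,
                    threshold_level=float("nan"),
                    n_objects=0,
                    mean_nucleus_area=None,
                    total_count=0,
                    trim_percent=config.trim_percent,
                    error=str(exc),
                )
            )
    if all(r.error is not None for r in rows):
        raise RuntimeError(f"every file in {config.input_dir} failed to process")
    return BatchReport(rows=rows)


def write_report(report: BatchReport, path) -> None:
    """Write the per-image report as CSV (one row per image, in order)."""
    path = Path(path)
    try:
        report.to_dataframe().to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write report {path}: {exc}") from exc
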