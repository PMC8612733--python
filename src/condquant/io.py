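"""Raster and table I/O plus run configuration.

Conventions used everywhere in the package:

* pixel coordinates are 0-based, row-major ``(row, col)``;
* intensities are unitless detector counts; the only photometric
  calibration applied anywhere is dark-frame (camera offset) subtraction;
* multi-page TIFFs become an :class:`ImageStack`, one page per frame, in
  file page order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import DimensionError, FormatError

__all__ = [
    "Image2D",
    "ImageStack",
    "RunConfig",
    "read_image",
    "write_image",
    "write_table",
    "read_table",
]


@dataclass
class Image2D:
    """A single-channel fluorescence image.

    Parameters
    ----------
    pixels
        2-D raster of non-negative, finite detector counts.
    pixel_size_um
        Physical length of one pixel edge in micrometres, if known.
    channel_name
        Free-text channel label (e.g. ``"GFP"``, ``"Cy5"``).
    """

    pixels: np.ndarray
    pixel_size_um: float | None = None
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise DimensionError(
                f"Image2D needs a 2-D raster, got ndim={self.pixels.ndim}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise FormatError("Image2D pixels must all be finite")
        if np.any(self.pixels < 0):
            raise FormatError("Image2D pixels must be non-negative counts")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ImageStack:
    """An ordered time-lapse of same-shaped :class:`Image2D` frames."""

    frames: list[Image2D]
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise FormatError("ImageStack needs at least one frame")
        if self.frame_interval_s <= 0:
            raise FormatError("frame_interval_s must be positive")
        shape0 = self.frames[0].shape
        for i, fr in enumerate(self.frames):
            if fr.shape != shape0:
                raise DimensionError(
                    f"frame {i} shape {fr.shape} differs from frame 0 {shape0}"
                )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class RunConfig:
    """Run configuration recorded alongside every result table."""

    seed: int = 0
    params: dict = field(default_factory=dict)
    out_dir: str = "."

    def config_hash(self) -> str:
        """Short stable hash of the parameter set (seed excluded)."""
        blob = json.dumps(self.params, sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            seed=int(data.get("seed", 0)),
            params=dict(data.get("params", {})),
            out_dir=str(data.get("out_dir", ".")),
        )


def read_image(
    path: str | Path,
    frame_interval_s: float = 1.0,
    pixel_size_um: float | None = None,
    channel_name: str = "",
) -> Image2D | ImageStack:
    """Read a single- or multi-page TIFF.

    Single-page files return an :class:`Image2D`; multi-page files return
    an :class:`ImageStack` with one frame per page (page order preserved).
    ``frame_interval_s`` is only used for stacks; TIFF timing metadata is
    not parsed.
    """
    path = Path(path)
    try:
        data = tifffile.imread(path)
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        return Image2D(data, pixel_size_um=pixel_size_um, channel_name=channel_name)
    if data.ndim == 3:
        frames = [
            Image2D(frame, pixel_size_um=pixel_size_um, channel_name=channel_name)
            for frame in data
        ]
        return ImageStack(frames, frame_interval_s=frame_interval_s)
    raise FormatError(f"{path}: unsupported TIFF dimensionality {data.ndim}")


def write_image(image: Image2D | ImageStack | np.ndarray, path: str | Path) -> None:
    """Write an image, stack, or bare label raster to TIFF."""
    path = Path(path)
    if isinstance(image, Image2D):
        data = image.pixels
    elif isinstance(image, ImageStack):
        data = np.stack([fr.pixels for fr in image.frames])
    else:
        data = np.asarray(image)
    try:
        tifffile.imwrite(path, data)
    except OSError as exc:
        raise FormatError(f"cannot write TIFF {path}: {exc}") from exc


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records.copy()
    records = list(records)
    if records and dataclasses.is_dataclass(records[0]):
        records = [dataclasses.asdict(r) for r in records]
    return pd.DataFrame(records)


def write_table(
    records,
    path: str | Path,
    run_config: RunConfig | None = None,
    allow_empty: bool = False,
) -> pd.DataFrame:
    """Write tabular results to CSV with a header row.

    Floats are rendered with Python's shortest round-trip repr so that
    re-reading the file reproduces the values bit-identically. When a
    :class:`RunConfig` is given, ``seed`` and ``config_hash`` columns are
    appended so every result table records its provenance.
    """
    df = _records_to_frame(records)
    if df.empty and not allow_empty:
        raise FormatError("refusing to write an empty table (allow_empty=False)")
    if run_config is not None:
        df["seed"] = run_config.seed
        df["config_hash"] = run_config.config_hash()
    try:
        # shortest round-trip repr so re-reading reproduces floats exactly
        df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))
    except OSError as exc:
        raise FormatError(f"cannot write CSV {path}: {exc}") from exc
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    try:
        # round_trip parsing so values written by write_table come back
        # bit-identically
        return pd.read_csv(path, float_precision="round_trip")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc
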