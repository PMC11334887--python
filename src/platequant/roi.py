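"""Headless circular-ROI color extraction from microplate photographs.

Images are 8-bit RGB arrays in image coordinates: origin top-left, x
rightward (columns), y downward (rows).  A well's region of interest is a
circle; the reading is the arithmetic per-channel mean over every pixel
whose integer center lies inside the closed disk
``(px-cx)^2 + (py-cy)^2 <= radius^2``.  Channel means are carried as real
values; output tables round to two decimals.

Pixel values are taken as stored (8-bit sRGB); no gamma linearization or
white-balance correction is applied — consistent lighting and camera white
balance are expected to be fixed at capture time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
from PIL import Image, ImageOps, UnidentifiedImageError

from .errors import (
    EmptyROIError,
    InputError,
    OutOfBoundsError,
    ROIError,
    SchemaError,
)
from .plate import WellAddress

CHANNELS = ("R", "G", "B")


def load_image(path: str | Path) -> np.ndarray:
    """Load a JPEG/PNG photograph as an (H, W, 3) uint8 RGB array.

    EXIF orientation is honored before pixel coordinates are interpreted.
    """
    try:
        with Image.open(path) as img:
            img = ImageOps.exif_transpose(img)
            return np.asarray(img.convert("RGB"), dtype=np.uint8)
    except (OSError, UnidentifiedImageError) as exc:
        raise InputError(f"cannot read image {path}: {exc}") from exc


@dataclass(frozen=True)
class CircleROI:
    """Circular region: center (cx, cy) and radius, in pixels."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ROIError(f"ROI radius must be > 0, got {self.radius}")


@dataclass(frozen=True)
class RGBTriple:
    """Per-channel mean intensities of a region, real-valued on 0-255."""

    r: float
    g: float
    b: float

    def __post_init__(self) -> None:
        for name, v in (("r", self.r), ("g", self.g), ("b", self.b)):
            if not (0.0 <= v <= 255.0):
                raise ROIError(f"channel {name} out of [0, 255]: {v}")

    def channel(self, name: str) -> float:
        name = str(name).upper()
        if name not in CHANNELS:
            raise SchemaError(f"unknown channel {name!r}; expected one of {CHANNELS}")
        return {"R": self.r, "G": self.g, "B": self.b}[name]

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r, self.g, self.b)


@dataclass(frozen=True)
class WellReading:
    """One well's extracted color, with optional paired absorbance."""

    well: WellAddress
    rgb: RGBTriple
    absorbance: float | None = None
    roi: CircleROI | None = None

    def __post_init__(self) -> None:
        if self.absorbance is not None and self.absorbance < 0:
            raise SchemaError(f"absorbance must be >= 0, got {self.absorbance}")


def circle_from_points(
    p1: tuple[float, float],
    p2: tuple[float, float],
    semantics: str = "center-edge",
) -> CircleROI:
    """Build a circle from the two designation clicks.

    ``center-edge`` (default): first point is the center, the second a point
    on the circumference.  ``diameter``: the points are opposite ends of a
    diameter.  Coincident points are rejected.
    """
    (x1, y1), (x2, y2) = p1, p2
    d = math.hypot(x2 - x1, y2 - y1)
    if d == 0:
        raise ROIError("the two points coincide; circle radius would be zero")
    if semantics == "center-edge":
        return CircleROI(float(x1), float(y1), d)
    if semantics == "diameter":
        return CircleROI((x1 + x2) / 2.0, (y1 + y2) / 2.0, d / 2.0)
    raise SchemaError(f"unknown circle semantics {semantics!r}")


def disk_mask(shape: tuple[int, int], roi: CircleROI) -> np.ndarray:
    """Boolean (H, W) mask of pixel centers inside the closed disk."""
    h, w = shape
    yy, xx = np.ogrid[0:h, 0:w]
    return (xx - roi.cx) ** 2 + (yy - roi.cy) ** 2 <= roi.radius**2


def _check_bounds(image: np.ndarray, roi: CircleROI) -> None:
    h, w = image.shape[:2]
    if (
        roi.cx - roi.radius < 0
        or roi.cy - roi.radius < 0
        or roi.cx + roi.radius > w - 1
        or roi.cy + roi.radius > h - 1
    ):
        raise OutOfBoundsError(
            f"circle (cx={roi.cx}, cy={roi.cy}, r={roi.radius}) exceeds "
            f"the {w}x{h} image bounds"
        )


def mean_rgb(image: np.ndarray, roi: CircleROI) -> RGBTriple:
    """Average RGB intensity within a circular region of the image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise InputError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    _check_bounds(image, roi)
    mask = disk_mask(image.shape[:2], roi)
    if not mask.any():
        raise EmptyROIError("no pixel center falls inside the circle")
    means = image[mask].astype(np.float64).mean(axis=0)
    return RGBTriple(float(means[0]), float(means[1]), float(means[2]))


def extract_plate(
    image: np.ndarray,
    rois: Mapping[WellAddress, CircleROI],
) -> list[WellReading]:
    """Extract one reading per well ROI, in row-major plate order.

    All ROIs are attempted; failures are aggregated into a single error
    naming the offending wells.
    """
    ordered = sorted(rois, key=lambda a: (a.row_index, a.column_index))
    readings: list[WellReading] = []
    failures: list[str] = []
    for addr in ordered:
        try:
            rgb = mean_rgb(image, rois[addr])
        except ROIError as exc:
            failures.append(f"{addr} ({exc})")
            continue
        readings.append(WellReading(well=addr, rgb=rgb, roi=rois[addr]))
    if failures:
        raise ROIError("ROI extraction failed for wells: " + "; ".join(failures))
    return readings


def select_channel(reading: WellReading, channel: str = "B") -> float:
    """The named channel's mean intensity (the blue B-value by default)."""
    return reading.rgb.channel(channel)


# ---------------------------------------------------------------------------
# Delimited-table I/O

def read_roi_table(source: str | Path | IO[str]) -> dict[WellAddress, CircleROI]:
    """Read ROIs from a table: ``well,cx,cy,radius`` or ``well,x1,y1,x2,y2``."""
    try:
        frame = pd.read_csv(source, skipinitialspace=True)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read ROI table: {exc}") from exc
    cols = set(frame.columns)
    rois: dict[WellAddress, CircleROI] = {}
    for i, row in frame.iterrows():
        try:
            addr = WellAddress.from_string(row["well"])
            if {"cx", "cy", "radius"} <= cols:
                roi = CircleROI(float(row["cx"]), float(row["cy"]), float(row["radius"]))
            elif {"x1", "y1", "x2", "y2"} <= cols:
                roi = circle_from_points(
                    (float(row["x1"]), float(row["y1"])),
                    (float(row["x2"]), float(row["y2"])),
                )
            else:
                raise InputError(
                    "ROI table needs columns well,cx,cy,radius or well,x1,y1,x2,y2"
                )
        except (KeyError, ValueError, TypeError) as exc:
            raise InputError(f"malformed ROI table row {i}: {exc}") from exc
        if addr in rois:
            raise InputError(f"duplicate well {addr} in ROI table (row {i})")
        rois[addr] = roi
    return rois


def write_readings(readings: list[WellReading], target: str | Path | IO[str]) -> None:
    """Write readings as ``well,r,g,b[,absorbance]`` (two-decimal channels)."""
    has_abs = any(r.absorbance is not None for r in readings)
    records = []
    for r in readings:
        rec = {
            "well": str(r.well),
            "r": round(r.rgb.r, 2),
            "g": round(r.rgb.g, 2),
            "b": round(r.rgb.b, 2),
        }
        if has_abs:
            rec["absorbance"] = r.absorbance
        records.append(rec)
    cols = ["well", "r", "g", "b"] + (["absorbance"] if has_abs else [])
    pd.DataFrame.from_records(records, columns=cols).to_csv(target, index=False)


def read_readings(source: str | Path | IO[str]) -> list[WellReading]:
    """Read a readings table written by :func:`write_readings`."""
    try:
        frame = pd.read_csv(source, skipinitialspace=True)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read readings table: {exc}") from exc
    missing = {"well", "r", "g", "b"} - set(frame.columns)
    if missing:
        raise InputError(f"readings table missing columns: {sorted(missing)}")
    readings = []
    for i, row in frame.iterrows():
        try:
            absorbance = None
            if "absorbance" in frame.columns and pd.notna(row["absorbance"]):
                absorbance = float(row["absorbance"])
            readings.append(
                WellReading(
                    well=WellAddress.from_string(row["well"]),
                    rgb=RGBTriple(float(row["r"]), float(row["g"]), float(row["b"])),
                    absorbance=absorbance,
                )
            )
        except (ValueError, TypeError) as exc:
            raise InputError(f"malformed readings row {i}: {exc}") from exc
    return readings
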