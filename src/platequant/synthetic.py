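"""Synthetic backlit-plate generator with ground truth.

Renders 96-well plate "photographs" from known protein concentrations and a
linear concentration->color response, so the extraction/calibration chain
can be exercised and validated without laboratory images.

The default blue-channel response follows the reference smartphone standard
curve, B = 113.25 + 0.8118 * conc (intensity units per μg/mL).  The red and
green channels decrease mildly with concentration — the CBBG-protein complex
is blue — with plausible invented parameters; only the B-value enters the
default analysis.  Measurement noise is i.i.d. Gaussian *per well* (the
analysis unit is the well mean), with optional per-pixel texture noise.
All randomness flows through one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Mapping

import numpy as np
import pandas as pd
from PIL import Image

from .errors import SchemaError
from .plate import PlateLayout, WellAddress
from .roi import CircleROI, RGBTriple, WellReading, disk_mask

DEFAULT_B_INTERCEPT = 113.25
DEFAULT_B_SLOPE = 0.8118


@dataclass(frozen=True)
class ColorResponseModel:
    """Linear per-channel concentration->intensity model with Gaussian noise."""

    b_intercept: float = DEFAULT_B_INTERCEPT
    b_slope: float = DEFAULT_B_SLOPE
    r_baseline: float = 180.0
    r_slope: float = -1.5
    g_baseline: float = 160.0
    g_slope: float = -0.8
    noise_sd: float = 1.0  # intensity units, per well and channel
    pixel_noise_sd: float = 0.0  # optional per-pixel texture

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.pixel_noise_sd < 0:
            raise SchemaError("noise standard deviations must be >= 0")


def apply_lighting(model: ColorResponseModel, preset: str) -> ColorResponseModel:
    """Shift model baselines/noise for a lighting condition.

    ``well_lit`` is the reference indoor condition; ``poor`` darkens the
    baseline and doubles noise; ``outdoor`` brightens and adds noise plus a
    slight green cast.  Presets shift intercepts and noise only — the slope
    (the chemistry) is unchanged.
    """
    if preset == "well_lit":
        return model
    if preset == "poor":
        return replace(model, b_intercept=model.b_intercept - 30.0, noise_sd=model.noise_sd * 2.0)
    if preset == "outdoor":
        return replace(
            model,
            b_intercept=model.b_intercept + 15.0,
            noise_sd=model.noise_sd * 1.5,
            g_baseline=model.g_baseline + 10.0,
        )
    raise SchemaError(f"unknown lighting preset {preset!r}")


LIGHTING_PRESETS = ("well_lit", "poor", "outdoor")


@dataclass(frozen=True)
class PlateRenderSpec:
    """Geometry and conditions for rendering a plate image."""

    width: int = 500
    height: int = 340
    pitch: float = 40.0  # well center spacing, pixels
    well_radius: float = 14.0
    margin: float = 30.0  # center of well A1 from the top-left corner
    background: tuple[int, int, int] = (235, 235, 238)
    lighting: str = "well_lit"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pitch <= 2 * self.well_radius:
            raise SchemaError("well pitch must exceed the well diameter")
        if self.lighting not in LIGHTING_PRESETS:
            raise SchemaError(f"unknown lighting preset {self.lighting!r}")

    def well_center(self, addr: WellAddress) -> tuple[float, float]:
        return (
            self.margin + addr.column_index * self.pitch,
            self.margin + addr.row_index * self.pitch,
        )

    def validate_fits(self, layout: PlateLayout) -> None:
        for addr in layout.sorted_wells():
            cx, cy = self.well_center(addr)
            if (
                cx - self.well_radius < 0
                or cy - self.well_radius < 0
                or cx + self.well_radius > self.width - 1
                or cy + self.well_radius > self.height - 1
            ):
                raise SchemaError(f"well {addr} does not fit inside the rendered image")


@dataclass(frozen=True)
class GroundTruthWell:
    well: WellAddress
    concentration: float
    color: RGBTriple  # pre-noise, pre-quantization model response
    roi: CircleROI


@dataclass
class GroundTruth:
    """Per-well truth for a rendered plate: concentration, color, ROI."""

    entries: list[GroundTruthWell] = field(default_factory=list)

    def rois(self) -> dict[WellAddress, CircleROI]:
        return {e.well: e.roi for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "well": str(e.well),
                    "conc": e.concentration,
                    "r": e.color.r,
                    "g": e.color.g,
                    "b": e.color.b,
                    "cx": e.roi.cx,
                    "cy": e.roi.cy,
                    "radius": e.roi.radius,
                }
                for e in self.entries
            ],
            columns=["well", "conc", "r", "g", "b", "cx", "cy", "radius"],
        )

    def write(self, target: str | Path | IO[str]) -> None:
        self.to_frame().to_csv(target, index=False)


def _clip255(x: float) -> float:
    return float(min(255.0, max(0.0, x)))


def response_color(
    conc: float,
    model: ColorResponseModel | None = None,
    rng: np.random.Generator | None = None,
) -> RGBTriple:
    """Model color of a well at a given concentration (μg/mL).

    With an ``rng``, adds per-well Gaussian noise (sd ``model.noise_sd``) to
    each channel; without one, returns the noiseless response.  Values are
    clipped to [0, 255] (quantization to 8 bits happens only at rendering).
    """
    if conc < 0:
        raise SchemaError(f"concentration must be >= 0, got {conc}")
    model = model or ColorResponseModel()
    r = model.r_baseline + model.r_slope * conc
    g = model.g_baseline + model.g_slope * conc
    b = model.b_intercept + model.b_slope * conc
    if rng is not None and model.noise_sd > 0:
        eps = rng.normal(0.0, model.noise_sd, size=3)
        r, g, b = r + eps[0], g + eps[1], b + eps[2]
    return RGBTriple(_clip255(r), _clip255(g), _clip255(b))


def _well_concentration(
    layout: PlateLayout,
    addr: WellAddress,
    sample_concentrations: Mapping[str, float] | None,
) -> float:
    role = layout.wells[addr]
    if role.kind == "blank":
        return 0.0
    if role.kind == "standard":
        return float(role.concentration)  # type: ignore[arg-type]
    if sample_concentrations is None or role.sample_id not in sample_concentrations:
        raise SchemaError(
            f"sample {role.sample_id!r} needs a true concentration "
            "(sample_concentrations argument) to be simulated"
        )
    return float(sample_concentrations[role.sample_id])


def render_plate(
    layout: PlateLayout,
    model: ColorResponseModel | None = None,
    spec: PlateRenderSpec | None = None,
    sample_concentrations: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a plate photograph and its ground truth.

    Each occupied well is painted as a filled disk of its (noisy, clipped,
    8-bit-quantized) response color on the uniform backlit background.
    Identical seeds give byte-identical images.
    """
    model = model or ColorResponseModel()
    spec = spec or PlateRenderSpec()
    spec.validate_fits(layout)
    model = apply_lighting(model, spec.lighting)
    rng = np.random.default_rng(spec.seed)

    image = np.empty((spec.height, spec.width, 3), dtype=np.uint8)
    image[:, :] = np.asarray(spec.background, dtype=np.uint8)
    truth = GroundTruth()

    for addr in layout.sorted_wells():
        conc = _well_concentration(layout, addr, sample_concentrations)
        clean = response_color(conc, model, rng=None)
        noisy = response_color(conc, model, rng=rng)
        cx, cy = spec.well_center(addr)
        roi = CircleROI(cx, cy, spec.well_radius)
        mask = disk_mask((spec.height, spec.width), roi)
        pixel = np.array(noisy.as_tuple(), dtype=np.float64)
        if model.pixel_noise_sd > 0:
            n = int(mask.sum())
            block = pixel + rng.normal(0.0, model.pixel_noise_sd, size=(n, 3))
            image[mask] = np.clip(np.rint(block), 0, 255).astype(np.uint8)
        else:
            image[mask] = np.clip(np.rint(pixel), 0, 255).astype(np.uint8)
        truth.entries.append(GroundTruthWell(addr, conc, clean, roi))

    return image, truth


def simulate_readings(
    layout: PlateLayout,
    model: ColorResponseModel | None = None,
    seed: int = 0,
    sample_concentrations: Mapping[str, float] | None = None,
) -> list[WellReading]:
    """Image-free fast path: draw one well reading per assigned well.

    Colors come straight from :func:`response_color` (no rendering, no 8-bit
    quantization), reproducibly for a given seed.
    """
    model = model or ColorResponseModel()
    rng = np.random.default_rng(seed)
    readings = []
    for addr in layout.sorted_wells():
        conc = _well_concentration(layout, addr, sample_concentrations)
        readings.append(WellReading(well=addr, rgb=response_color(conc, model, rng=rng)))
    return readings


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write a rendered plate as PNG."""
    Image.fromarray(image, mode="RGB").save(path, format="PNG")
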