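"""Bundled text fixtures: reference price table, reference standard curves,
published validation summary, and a default plate layout."""

from __future__ import annotations

import json
from importlib import resources

from ..calibration import CalibrationCurve
from ..cost import CostItem, read_price_table
from ..plate import PlateLayout, parse_layout

PRICE_TABLE = "assay_prices_cny.csv"
REFERENCE_CURVES = "reference_curves.json"
VALIDATION_SUMMARY = "validation_summary.json"
DEFAULT_LAYOUT = "default_layout.csv"


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def price_table_path():
    """Filesystem path of the bundled assay price table (CNY)."""
    return _path(PRICE_TABLE)


def load_price_table(share_denominator: int | None = None) -> list[CostItem]:
    with resources.as_file(_path(PRICE_TABLE)) as p:
        return read_price_table(p, share_denominator=share_denominator)


def load_reference_curves() -> dict[tuple[str, str], CalibrationCurve]:
    """Reference standard curves keyed by (method, sample id).

    RMSE fields are not published for these curves and load as NaN.
    """
    payload = json.loads(_path(REFERENCE_CURVES).read_text())
    return {(c["method"], c["sample"]): CalibrationCurve.from_dict(c) for c in payload}


def load_validation_summary() -> dict:
    """Published validation numbers (RSDs, LOD, recoveries, replicate SDs)."""
    return json.loads(_path(VALIDATION_SUMMARY).read_text())


def load_default_layout() -> PlateLayout:
    """Default plate layout: 5 standards (0-20 μg/mL) + 2 triplicate samples."""
    with resources.as_file(_path(DEFAULT_LAYOUT)) as p:
        return parse_layout(p)


def default_layout_path():
    return _path(DEFAULT_LAYOUT)
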