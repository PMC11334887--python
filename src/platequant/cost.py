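"""Itemized per-test cost accounting for the assay.

Each item is priced as

    price/test = market_price / package_quantity * units_per_test / share

where ``share`` spreads plate-level items over the usable wells (default 91
of 96: five wells per plate carry the calibration standards, so the
remaining samples share those costs).  Unit algebra covers mass (mg/g/kg),
volume (μL/mL/L) and counts; amounts are exact rationals internally and are
displayed half-up at 3 decimals.

Price tables may carry the vendor's printed per-test price alongside the
raw columns; the report recomputes every row and flags any disagreement at
the third decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from pathlib import Path
from typing import IO, Sequence

import pandas as pd

from .errors import InputError, SchemaError, UnitError

# unit -> (dimension, factor to the base unit: mg, μL or count)
_UNITS: dict[str, tuple[str, Fraction]] = {
    "mg": ("mass", Fraction(1)),
    "g": ("mass", Fraction(1000)),
    "kg": ("mass", Fraction(1_000_000)),
    "ul": ("volume", Fraction(1)),
    "ml": ("volume", Fraction(1000)),
    "l": ("volume", Fraction(1_000_000)),
    "count": ("count", Fraction(1)),
    "unit": ("count", Fraction(1)),
    "piece": ("count", Fraction(1)),
    "": ("count", Fraction(1)),
}


def _normalize_unit(unit: str) -> str:
    u = str(unit).strip().lower().replace("µ", "u").replace("μ", "u")
    if u not in _UNITS:
        raise UnitError(f"unknown unit {unit!r}")
    return u


def _fraction(value) -> Fraction:
    try:
        return Fraction(str(value).strip())
    except (ValueError, ZeroDivisionError) as exc:
        raise SchemaError(f"cannot parse amount {value!r}") from exc


@dataclass(frozen=True)
class Quantity:
    """Amount plus unit; amounts are exact rationals."""

    amount: Fraction
    unit: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", _normalize_unit(self.unit))
        if self.amount < 0:
            raise SchemaError(f"quantity amount must be >= 0, got {self.amount}")

    @property
    def dimension(self) -> str:
        return _UNITS[self.unit][0]

    @property
    def base_amount(self) -> Fraction:
        return self.amount * _UNITS[self.unit][1]


CATEGORIES = ("chemical", "consumable")


@dataclass(frozen=True)
class CostItem:
    """One reagent or consumable row of the price table."""

    name: str
    category: str
    market_price: Fraction  # currency units per package
    package_quantity: Quantity
    units_per_test: Quantity
    share_denominator: int = 1  # e.g. 91 for per-plate shared items
    printed_price_per_test: Decimal | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(f"category must be one of {CATEGORIES}, got {self.category!r}")
        if self.market_price < 0:
            raise SchemaError("market_price must be >= 0")
        if self.package_quantity.base_amount <= 0:
            raise SchemaError("package_quantity must be > 0")
        if self.share_denominator < 1:
            raise SchemaError("share_denominator must be >= 1")


def item_cost(item: CostItem) -> Fraction:
    """Exact per-test price of one item (currency units)."""
    if item.package_quantity.dimension != item.units_per_test.dimension:
        raise UnitError(
            f"{item.name}: package unit {item.package_quantity.unit!r} is not "
            f"commensurable with per-test unit {item.units_per_test.unit!r}"
        )
    return (
        item.market_price
        / item.package_quantity.base_amount
        * item.units_per_test.base_amount
        / item.share_denominator
    )


def display_price(value: Fraction | Decimal, ndigits: int = 3) -> Decimal:
    """Half-up display rounding at 3 decimals."""
    if isinstance(value, Fraction):
        value = Decimal(value.numerator) / Decimal(value.denominator)
    return value.quantize(Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP)


@dataclass
class CostReportRow:
    name: str
    category: str
    price_per_test: Fraction
    printed_price_per_test: Decimal | None = None

    @property
    def discrepancy(self) -> bool:
        """True when the recomputed price disagrees with the printed one at 3 dp."""
        if self.printed_price_per_test is None:
            return False
        return display_price(self.price_per_test) != self.printed_price_per_test


@dataclass
class CostReport:
    """Per-item and total per-test prices."""

    rows: list[CostReportRow]
    currency: str = "CNY"

    @property
    def total(self) -> Fraction:
        return sum((r.price_per_test for r in self.rows), Fraction(0))

    @property
    def printed_total(self) -> Decimal | None:
        """Sum of the printed per-test prices, when every row carries one."""
        printed = [r.printed_price_per_test for r in self.rows]
        if any(p is None for p in printed):
            return None
        return sum(printed, Decimal(0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            [
                {
                    "name": r.name,
                    "category": r.category,
                    "price_per_test": float(display_price(r.price_per_test)),
                    "printed_price_per_test": (
                        float(r.printed_price_per_test)
                        if r.printed_price_per_test is not None
                        else None
                    ),
                    "discrepancy": r.discrepancy,
                }
                for r in self.rows
            ],
            columns=["name", "category", "price_per_test", "printed_price_per_test", "discrepancy"],
        )

    def to_dict(self) -> dict:
        return {
            "currency": self.currency,
            "items": self.to_frame().to_dict(orient="records"),
            "total_per_test": float(display_price(self.total)),
            "printed_total_per_test": (
                float(self.printed_total) if self.printed_total is not None else None
            ),
        }


def total_cost(items: Sequence[CostItem] | Sequence[float], currency: str = "CNY") -> CostReport:
    """Total per-test cost from CostItems or precomputed per-test prices."""
    items = list(items)
    if not items:
        raise SchemaError("cost report needs at least one item")
    rows: list[CostReportRow] = []
    for i, item in enumerate(items):
        if isinstance(item, CostItem):
            rows.append(
                CostReportRow(
                    name=item.name,
                    category=item.category,
                    price_per_test=item_cost(item),
                    printed_price_per_test=item.printed_price_per_test,
                )
            )
        else:
            price = Fraction(str(item))
            rows.append(CostReportRow(name=f"item_{i + 1}", category="chemical", price_per_test=price))
    return CostReport(rows=rows, currency=currency)


PRICE_TABLE_COLUMNS = [
    "name", "category", "market_price", "package_qty", "package_unit",
    "per_test_qty", "per_test_unit", "share_denominator",
]


def read_price_table(
    source: str | Path | IO[str],
    share_denominator: int | None = None,
) -> list[CostItem]:
    """Read a price table (see ``PRICE_TABLE_COLUMNS``; optional
    ``printed_price_per_test`` column).

    ``share_denominator``, when given, overrides the sharing denominator of
    every plate-shared row (rows whose own denominator exceeds 1) — e.g. for
    layouts reserving a different number of wells for standards.
    """
    try:
        frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read price table: {exc}") from exc
    if frame.empty:
        raise SchemaError("price table is empty")
    missing = set(PRICE_TABLE_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"price table missing columns: {sorted(missing)}")
    items: list[CostItem] = []
    for i, row in frame.iterrows():
        try:
            share = int(row["share_denominator"])
            if share_denominator is not None and share > 1:
                share = int(share_denominator)
            printed = None
            if "printed_price_per_test" in frame.columns and pd.notna(row["printed_price_per_test"]):
                printed = Decimal(str(row["printed_price_per_test"]).strip())
            items.append(
                CostItem(
                    name=str(row["name"]).strip(),
                    category=str(row["category"]).strip().lower(),
                    market_price=_fraction(row["market_price"]),
                    package_quantity=Quantity(_fraction(row["package_qty"]), row["package_unit"]),
                    units_per_test=Quantity(_fraction(row["per_test_qty"]), row["per_test_unit"]),
                    share_denominator=share,
                    printed_price_per_test=printed,
                )
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise InputError(f"malformed price table row {i}: {exc}") from exc
    return items


def write_report(report: CostReport, csv_target=None, json_target=None) -> None:
    frame = report.to_frame()
    if csv_target is not None:
        frame.to_csv(csv_target, index=False)
    if json_target is not None:
        payload = json.dumps(report.to_dict(), indent=2)
        if hasattr(json_target, "write"):
            json_target.write(payload)
        else:
            Path(json_target).write_text(payload)
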