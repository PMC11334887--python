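"""Plate-domain types: well addresses, roles, layouts, standard series and
the dilution scheme that links extract concentration to dry-weight content.

A 96-well microplate is addressed row-letter (A-H) + 1-based column (1-12),
rendered ``"A1"`` and ordered row-major, the universal plate convention.
Each well is either a *blank*, a *standard* at a known concentration
(μg/mL of protein in the pre-dye analyte), or a *sample* replicate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .errors import InputError, InvalidSeriesError, LayoutError, SchemaError

ROW_LETTERS = "ABCDEFGH"
N_COLUMNS = 12

LAYOUT_COLUMNS = ["well", "role", "concentration", "sample_id", "replicate"]


@dataclass(frozen=True, order=True)
class WellAddress:
    """A single well, e.g. ``WellAddress("A", 1)`` rendered as ``"A1"``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROW_LETTERS:
            raise LayoutError(f"well row must be one of {ROW_LETTERS!r}, got {self.row!r}")
        if not (1 <= int(self.column) <= N_COLUMNS):
            raise LayoutError(f"well column must be 1..{N_COLUMNS}, got {self.column!r}")

    @classmethod
    def from_string(cls, text: str) -> "WellAddress":
        text = str(text).strip().upper()
        if len(text) < 2:
            raise LayoutError(f"unparsable well address {text!r}")
        row, col = text[0], text[1:]
        try:
            column = int(col)
        except ValueError as exc:
            raise LayoutError(f"unparsable well address {text!r}") from exc
        return cls(row, column)

    def __str__(self) -> str:
        return f"{self.row}{self.column}"

    @property
    def row_index(self) -> int:
        """0-based row index (A -> 0)."""
        return ROW_LETTERS.index(self.row)

    @property
    def column_index(self) -> int:
        """0-based column index (1 -> 0)."""
        return self.column - 1


ROLE_KINDS = ("blank", "standard", "sample")


@dataclass(frozen=True)
class WellRole:
    """What a well contains.

    * ``standard`` requires ``concentration`` (μg/mL, >= 0);
    * ``sample`` requires ``sample_id`` (replicate index optional);
    * ``blank`` carries neither.
    """

    kind: str
    concentration: float | None = None
    sample_id: str | None = None
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ROLE_KINDS:
            raise LayoutError(f"unknown well role {self.kind!r}")
        if self.kind == "standard":
            if self.concentration is None:
                raise LayoutError("standard wells require a concentration")
            if self.concentration < 0:
                raise LayoutError("standard concentration must be >= 0")
            if self.sample_id is not None:
                raise LayoutError("standard wells carry no sample_id")
        elif self.kind == "sample":
            if self.sample_id is None:
                raise LayoutError("sample wells require a sample_id")
            if self.concentration is not None:
                raise LayoutError("sample wells carry no known concentration")
        else:  # blank
            if self.concentration is not None or self.sample_id is not None:
                raise LayoutError("blank wells carry neither concentration nor sample_id")


@dataclass
class PlateLayout:
    """Mapping of occupied wells to their roles on an (up to) 8x12 plate."""

    wells: dict[WellAddress, WellRole] = field(default_factory=dict)
    n_rows: int = 8
    n_cols: int = 12

    def __post_init__(self) -> None:
        if not (1 <= self.n_rows <= 8 and 1 <= self.n_cols <= 12):
            raise LayoutError("plate shape limited to at most 8x12")
        for addr in self.wells:
            if addr.row_index >= self.n_rows or addr.column_index >= self.n_cols:
                raise LayoutError(f"well {addr} outside the {self.n_rows}x{self.n_cols} plate")

    def sorted_wells(self) -> list[WellAddress]:
        """Occupied wells in row-major plate order."""
        return sorted(self.wells, key=lambda a: (a.row_index, a.column_index))

    def standards(self) -> list[tuple[WellAddress, float]]:
        return [
            (a, self.wells[a].concentration)  # type: ignore[misc]
            for a in self.sorted_wells()
            if self.wells[a].kind == "standard"
        ]

    def blanks(self) -> list[WellAddress]:
        return [a for a in self.sorted_wells() if self.wells[a].kind == "blank"]

    def samples(self) -> dict[str, list[WellAddress]]:
        """Sample wells grouped by sample_id, replicates in plate order."""
        groups: dict[str, list[WellAddress]] = {}
        for addr in self.sorted_wells():
            role = self.wells[addr]
            if role.kind == "sample":
                groups.setdefault(role.sample_id, []).append(addr)  # type: ignore[arg-type]
        return groups

    def standard_concentrations(self) -> list[float]:
        return sorted({c for _, c in self.standards()})

    def require_calibratable(self) -> None:
        """Calibration needs at least two distinct standard concentrations."""
        if len(self.standard_concentrations()) < 2:
            raise LayoutError("layout needs >= 2 distinct standard concentrations for calibration")


@dataclass(frozen=True)
class StandardSeries:
    """Ordered concentration series (μg/mL): strictly monotone, non-negative.

    Increasing series are calibration gradients; decreasing series are
    detection-limit dilution walks.
    """

    levels: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.levels) == 0:
            raise InvalidSeriesError("series must contain at least one level")
        if any(c < 0 for c in self.levels):
            raise InvalidSeriesError("concentrations must be non-negative")
        if len(self.levels) > 1:
            diffs = [b - a for a, b in zip(self.levels, self.levels[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                raise InvalidSeriesError("series must be strictly monotone")

    def __len__(self) -> int:
        return len(self.levels)

    def __iter__(self):
        return iter(self.levels)

    @property
    def increasing(self) -> bool:
        return len(self.levels) < 2 or self.levels[1] > self.levels[0]


def make_standard_series(start: float, stop: float, step: float) -> StandardSeries:
    """Arithmetic calibration series ``start, start+step, ..., stop`` inclusive.

    The default assay gradient is 0-20 μg/mL at a 5 μg/mL interval
    (five standard levels, the blank counted as the 0 μg/mL point).
    """
    if step <= 0:
        raise InvalidSeriesError("step must be > 0")
    if stop < start or start < 0:
        raise InvalidSeriesError("need stop >= start >= 0")
    n = int(math.floor((stop - start) / step + 1e-9)) + 1
    return StandardSeries(tuple(start + i * step for i in range(n)))


def make_twofold_series(start: float, n_levels: int) -> StandardSeries:
    """Decreasing two-fold dilution series of length ``n_levels`` from ``start``.

    Used for the detection-limit walk-down, e.g. ``(4.0, 5)`` gives
    4.0, 2.0, 1.0, 0.5, 0.25 μg/mL.
    """
    if start <= 0:
        raise InvalidSeriesError("start must be > 0")
    if int(n_levels) < 1:
        raise InvalidSeriesError("n_levels must be >= 1")
    return StandardSeries(tuple(start / 2**i for i in range(int(n_levels))))


@dataclass(frozen=True)
class DilutionScheme:
    """Masses and volumes converting extract concentration to dry-weight content.

    Defaults follow the assay workflow: 0.1 g of freeze-dried powder extracted
    in 5 mL water; a 20 μL aliquot of the extract diluted to 1000 μL; 1 mL of
    diluted analyte stained with 4 mL of CBBG solution.  Dye addition is
    identical for standards and samples, so it cancels out of quantification.
    """

    sample_mass: float = 0.1  # g
    extract_volume: float = 5.0  # mL
    aliquot_volume: float = 20.0  # μL
    final_volume: float = 1000.0  # μL
    dye_volume: float = 4.0  # mL
    analyte_volume: float = 1.0  # mL

    def __post_init__(self) -> None:
        for name in ("sample_mass", "extract_volume", "aliquot_volume",
                     "final_volume", "dye_volume", "analyte_volume"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"DilutionScheme.{name} must be > 0")
        if self.aliquot_volume > self.final_volume:
            raise SchemaError("aliquot_volume must not exceed final_volume")

    @property
    def dilution_factor(self) -> float:
        """Fold-dilution of the extract before staining (final/aliquot)."""
        return self.final_volume / self.aliquot_volume


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    return float(text)


def parse_layout(source: str | Path | IO[str]) -> PlateLayout:
    """Read a plate layout from a delimited table.

    Expected header: ``well,role,concentration,sample_id,replicate``
    (concentration for standards, sample_id/replicate for samples).
    Duplicate wells, out-of-range addresses and unknown roles are rejected.
    """
    try:
        frame = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise InputError(f"cannot read layout table: {exc}") from exc
    if frame.empty:
        raise LayoutError("layout table is empty")
    missing = {"well", "role"} - set(frame.columns)
    if missing:
        raise LayoutError(f"layout table missing columns: {sorted(missing)}")

    wells: dict[WellAddress, WellRole] = {}
    for i, row in frame.iterrows():
        addr = WellAddress.from_string(row["well"])
        if addr in wells:
            raise LayoutError(f"duplicate well {addr} in layout (row {i})")
        kind = str(row["role"]).strip().lower()
        conc = _parse_optional_float(row.get("concentration"))
        sample_id = row.get("sample_id")
        if sample_id is not None and (not isinstance(sample_id, str) or sample_id.strip() == ""):
            sample_id = None
        rep = _parse_optional_float(row.get("replicate"))
        wells[addr] = WellRole(
            kind=kind,
            concentration=conc,
            sample_id=sample_id.strip() if isinstance(sample_id, str) else None,
            replicate=int(rep) if rep is not None else None,
        )
    return PlateLayout(wells)


def write_layout(layout: PlateLayout, target: str | Path | IO[str]) -> None:
    """Write a layout back to its delimited-table form (parse round-trips)."""
    records = []
    for addr in layout.sorted_wells():
        role = layout.wells[addr]
        records.append(
            {
                "well": str(addr),
                "role": role.kind,
                "concentration": role.concentration,
                "sample_id": role.sample_id,
                "replicate": role.replicate,
            }
        )
    pd.DataFrame.from_records(records, columns=LAYOUT_COLUMNS).to_csv(target, index=False)


def layout_from_series(
    series: Iterable[float],
    start_well: str = "A1",
    axis: str = "row",
) -> PlateLayout:
    """Lay a concentration series onto consecutive wells (standards only).

    Convenience for simulations: places each level of ``series`` from
    ``start_well`` along a row (``axis="row"``) or down a column.
    """
    first = WellAddress.from_string(start_well)
    wells: dict[WellAddress, WellRole] = {}
    for i, conc in enumerate(series):
        if axis == "row":
            addr = WellAddress(first.row, first.column + i)
        elif axis == "column":
            addr = WellAddress(ROW_LETTERS[first.row_index + i], first.column)
        else:
            raise SchemaError(f"axis must be 'row' or 'column', got {axis!r}")
        wells[addr] = WellRole("standard", concentration=float(conc))
    return PlateLayout(wells)
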