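"""Replicate aggregation, outlier screening, content conversion, spike
recovery and method comparison.

Concentrations from the standard curve refer to the diluted analyte
(μg/mL); the dilution scheme maps them back to protein content per dry
sample mass:

    content [g/100 g] = conc * (final/aliquot) * extract_volume / sample_mass * 1e-4

Dye addition cancels because standards and samples are stained identically.
Report tables round half-up: content and RSD to 1 decimal, recovery to 1
decimal with a nearest-integer summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, LinearCalibrator, fit_linear, inverse_predict
from .errors import QCError, SchemaError
from .plate import DilutionScheme, PlateLayout
from .roi import WellReading, select_channel


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Replicates

@dataclass
class ReplicateSummary:
    """Mean, sample SD (n-1) and relative SD of replicate values."""

    mean: float
    sd: float
    rsd_percent: float
    n: int
    excluded_indices: tuple[int, ...] = ()


# Dixon's Q (r10) critical values for n = 3..7.
DIXON_Q_CRITICAL = {
    0.90: {3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507},
    0.95: {3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568},
    0.99: {3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680},
}


def screen_outlier(
    values: Sequence[float],
    method: str = "dixon_q",
    confidence: float = 0.95,
) -> int | None:
    """Flag at most one outlier among 3-7 replicates with Dixon's Q test.

    Q = (gap of the suspect extreme) / range, compared with the tabulated
    critical value.  Returns the index (into ``values``) of the excluded
    replicate, or None.  ``method="none"`` never excludes.
    """
    if method == "none":
        return None
    if method != "dixon_q":
        raise SchemaError(f"unknown outlier method {method!r}")
    if confidence not in DIXON_Q_CRITICAL:
        raise SchemaError(f"confidence must be one of {sorted(DIXON_Q_CRITICAL)}")
    x = np.asarray(values, dtype=float)
    n = x.size
    if not (3 <= n <= 7):
        raise QCError(f"Dixon's Q requires 3 <= n <= 7 replicates, got {n}")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rng = xs[-1] - xs[0]
    if rng == 0:
        return None
    q_low = (xs[1] - xs[0]) / rng
    q_high = (xs[-1] - xs[-2]) / rng
    q_crit = DIXON_Q_CRITICAL[confidence][n]
    if q_high >= q_low:
        return int(order[-1]) if q_high > q_crit else None
    return int(order[0]) if q_low > q_crit else None


def aggregate_replicates(
    values: Sequence[float],
    outlier: str = "none",
    confidence: float = 0.95,
) -> ReplicateSummary:
    """Mean / sample SD / RSD% of replicates, with optional Dixon screening.

    Outlier screening is off by default and, when requested, excludes at
    most one replicate before aggregation.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise QCError(f"need >= 2 replicates, got {x.size}")
    excluded: tuple[int, ...] = ()
    if outlier != "none":
        idx = screen_outlier(x, method=outlier, confidence=confidence)
        if idx is not None:
            excluded = (idx,)
            x = np.delete(x, idx)
            if x.size < 2:
                raise QCError("outlier exclusion left fewer than 2 replicates")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if mean == 0.0:
        if sd > 0:
            raise QCError("RSD undefined: replicate mean is zero")
        rsd = 0.0
    else:
        rsd = 100.0 * sd / mean
    return ReplicateSummary(mean=mean, sd=sd, rsd_percent=rsd, n=int(x.size), excluded_indices=excluded)


# ---------------------------------------------------------------------------
# Content conversion and recovery

def content_from_concentration(conc: float, scheme: DilutionScheme | None = None) -> float:
    """Dry-weight protein content (g/100 g) from analyte concentration (μg/mL).

    With the default scheme (50x dilution, 5 mL extract, 0.1 g powder),
    6 μg/mL maps to 1.5 g/100 g.
    """
    if conc < 0:
        raise QCError(f"concentration must be >= 0, got {conc}")
    scheme = scheme or DilutionScheme()
    # μg/mL * fold-dilution * mL / g = μg/g; 1e-4 converts μg/g to g/100 g.
    return conc * scheme.dilution_factor * scheme.extract_volume / scheme.sample_mass * 1e-4


def recovery(measured_spiked: float, measured_base: float, spiked_amount: float) -> float:
    """Spike recovery percentage: 100 * (spiked - base) / added."""
    if spiked_amount <= 0:
        raise QCError(f"spiked amount must be > 0, got {spiked_amount}")
    return 100.0 * (measured_spiked - measured_base) / spiked_amount


def protein_mass_mg(conc: float, extract_volume_ml: float, dilution_factor: float = 1.0) -> float:
    """Total protein mass (mg) in an extract from its measured concentration.

    ``dilution_factor`` is the user-declared fold-dilution applied before
    staining (spiked extracts typically exceed the 0-20 μg/mL curve range
    and must be diluted into it).
    """
    if conc < 0 or extract_volume_ml <= 0 or dilution_factor <= 0:
        raise QCError("conc must be >= 0 and volumes/dilutions > 0")
    return conc * dilution_factor * extract_volume_ml / 1000.0


# ---------------------------------------------------------------------------
# Method comparison

@dataclass
class MethodComparison:
    """Replicate-precision comparison across measurement methods.

    ``mean_sd`` averages each method's (unrounded) replicate SDs;
    ``differences`` holds per-sample mean differences of every method
    against the first label.
    """

    methods: tuple[str, ...]
    mean_sd: dict[str, float]
    differences: dict[str, list[float]] = field(default_factory=dict)


def compare_methods(
    summaries_by_method: Mapping[str, Sequence[ReplicateSummary]],
) -> MethodComparison:
    """Compare per-sample replicate summaries between matched methods."""
    if not summaries_by_method:
        raise QCError("need at least one method")
    methods = tuple(summaries_by_method)
    lengths = {m: len(summaries_by_method[m]) for m in methods}
    if len(set(lengths.values())) != 1 or next(iter(lengths.values())) == 0:
        raise QCError(f"methods must cover the same non-empty sample set, got sizes {lengths}")
    mean_sd = {m: float(np.mean([s.sd for s in summaries_by_method[m]])) for m in methods}
    ref = summaries_by_method[methods[0]]
    differences = {
        m: [s.mean - r.mean for s, r in zip(summaries_by_method[m], ref)]
        for m in methods[1:]
    }
    return MethodComparison(methods=methods, mean_sd=mean_sd, differences=differences)


# ---------------------------------------------------------------------------
# Plate-level quantification pipeline

def response_value(reading: WellReading, mode: str = "B") -> float:
    """Response of a reading under the chosen mode (color channel or absorbance)."""
    if mode == "absorbance":
        if reading.absorbance is None:
            raise SchemaError(f"well {reading.well} has no absorbance value")
        return reading.absorbance
    return select_channel(reading, mode)


def calibrate_from_layout(
    readings: Sequence[WellReading],
    layout: PlateLayout,
    mode: str = "B",
    rmse_denominator: str = "n",
) -> CalibrationCurve:
    """Fit the standard curve from a plate's standard wells.

    Blank wells are included as 0 μg/mL calibration points (no blank
    subtraction).
    """
    layout.require_calibratable()
    by_well = {r.well: r for r in readings}
    concs, resps = [], []
    for addr, conc in layout.standards():
        if addr not in by_well:
            raise SchemaError(f"standard well {addr} missing from readings")
        concs.append(conc)
        resps.append(response_value(by_well[addr], mode))
    for addr in layout.blanks():
        if addr in by_well:
            concs.append(0.0)
            resps.append(response_value(by_well[addr], mode))
    return fit_linear(concs, resps, channel_or_mode=mode, rmse_denominator=rmse_denominator)


def quantify_plate(
    readings: Sequence[WellReading],
    layout: PlateLayout,
    curve: CalibrationCurve | None = None,
    mode: str = "B",
    scheme: DilutionScheme | None = None,
    outlier: str = "none",
    confidence: float = 0.95,
) -> tuple[pd.DataFrame, CalibrationCurve]:
    """Quantify every sample on a plate.

    Fits the standard curve from the layout's standards unless ``curve`` is
    given, inverse-predicts each sample replicate, aggregates per sample and
    converts to dry-weight content.  Returns (results table, curve); the
    table reports unrounded values plus display-rounded content/RSD columns.
    """
    scheme = scheme or DilutionScheme()
    if curve is None:
        curve = calibrate_from_layout(readings, layout, mode=mode)
    by_well = {r.well: r for r in readings}
    content_per_unit = content_from_concentration(1.0, scheme)

    records = []
    for sample_id, wells in layout.samples().items():
        missing = [str(w) for w in wells if w not in by_well]
        if missing:
            raise SchemaError(f"sample {sample_id!r} wells missing from readings: {missing}")
        concs = [inverse_predict(curve, response_value(by_well[w], mode)) for w in wells]
        summary = aggregate_replicates(concs, outlier=outlier, confidence=confidence)
        mean_content = summary.mean * content_per_unit
        sd_content = summary.sd * content_per_unit
        records.append(
            {
                "sample_id": sample_id,
                "n": summary.n,
                "mean_conc": summary.mean,
                "mean_content": mean_content,
                "sd_content": sd_content,
                "rsd_percent": summary.rsd_percent,
                "content_1dp": round_half_up(mean_content, 1),
                "sd_1dp": round_half_up(sd_content, 1),
                "rsd_1dp": round_half_up(summary.rsd_percent, 1) if summary.mean != 0 else 0.0,
                "excluded": ";".join(str(wells[i]) for i in summary.excluded_indices),
                "below_blank": bool(summary.mean < 0),
            }
        )
    frame = pd.DataFrame.from_records(
        records,
        columns=[
            "sample_id", "n", "mean_conc", "mean_content", "sd_content",
            "rsd_percent", "content_1dp", "sd_1dp", "rsd_1dp", "excluded", "below_blank",
        ],
    )
    return frame, curve
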