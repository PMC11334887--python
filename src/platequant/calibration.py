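"""Standard-curve calibration, inverse prediction and detection limits.

The standard curve is an ordinary least-squares line of response (B-value or
absorbance) on protein concentration, with quality metrics:

* ``r_squared``   1 - SSres/SStot
* ``rmse``        sqrt(SSres / n)   (denominator n by default, so a perfect
  fit has RMSE exactly 0 regardless of n; ``n-2`` available)
* ``rrmse_percent``  100 * rmse / mean(response) — the package's relative
  RMSE definition (the denominator is a configurable choice).

Unknowns are quantified by inverse prediction, (response - intercept)/slope;
values below the blank come out negative and are flagged, never clamped.

The limit of detection is estimated by walking a strictly decreasing
dilution series down from the top: each level is compared with the blank
replicates by a one-sided Welch two-sample t-test (direction given by the
calibration slope sign), and the LOD is the lowest concentration such that
it *and every higher level* are distinguishable — an isolated rejection
below a non-significant level does not set the LOD.  The limit of
quantification is defined as exactly three times the LOD.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import FitError, InputError, SchemaError, UndetectableError

RESPONSE_MODES = ("B", "R", "G", "absorbance")


@dataclass
class CalibrationCurve:
    """Fitted standard curve with its quality metrics."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float
    rrmse_percent: float
    n_points: int
    channel_or_mode: str = "B"

    def __post_init__(self) -> None:
        if self.channel_or_mode not in RESPONSE_MODES:
            raise SchemaError(
                f"channel_or_mode must be one of {RESPONSE_MODES}, got {self.channel_or_mode!r}"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_dict(cls, payload: Mapping) -> "CalibrationCurve":
        try:
            return cls(
                slope=float(payload["slope"]),
                intercept=float(payload["intercept"]),
                r_squared=float(payload["r_squared"]),
                rmse=float(payload.get("rmse", float("nan"))),
                rrmse_percent=float(payload.get("rrmse_percent", float("nan"))),
                n_points=int(payload.get("n_points", 0)),
                channel_or_mode=str(payload.get("channel_or_mode", "B")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise InputError(f"malformed curve JSON: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationCurve":
        try:
            return cls.from_dict(json.loads(Path(path).read_text()))
        except (OSError, json.JSONDecodeError) as exc:
            raise InputError(f"cannot read curve JSON {path}: {exc}") from exc


class LinearCalibrator(BaseEstimator):
    """Sklearn-style estimator for the response-vs-concentration line.

    ``fit(X, y)`` takes concentrations (μg/mL; 1-D or a single column) and
    responses.  ``predict`` maps concentration to expected response;
    ``inverse_predict`` maps measured response back to concentration.

    Fitted attributes: ``slope_``, ``intercept_``, ``r_squared_``, ``rmse_``,
    ``rrmse_percent_``, ``n_points_``.

    Parameters
    ----------
    channel : str
        Response mode label carried into the exported curve ("B", "R", "G"
        or "absorbance"); does not affect the numerics.
    rmse_denominator : {"n", "n-2"}
        Divisor in the RMSE; "n" (default) makes a perfect fit report 0.
    """

    def __init__(self, channel: str = "B", rmse_denominator: str = "n"):
        self.channel = channel
        self.rmse_denominator = rmse_denominator

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise FitError(f"expected 1-D concentrations, got shape {x.shape}")
        return x

    def fit(self, X, y) -> "LinearCalibrator":
        if self.rmse_denominator not in ("n", "n-2"):
            raise SchemaError("rmse_denominator must be 'n' or 'n-2'")
        if self.channel not in RESPONSE_MODES:
            raise SchemaError(f"channel must be one of {RESPONSE_MODES}")
        x = self._as_1d(X)
        resp = np.asarray(y, dtype=float)
        if resp.shape != x.shape:
            raise FitError("concentrations and responses differ in length")
        n = x.size
        if n < 3:
            raise FitError(f"calibration needs >= 3 points, got {n}")
        if np.unique(x).size < 2:
            raise FitError("calibration needs >= 2 distinct concentrations")

        if np.ptp(resp) == 0:
            slope, intercept = 0.0, float(resp[0])
        else:
            res = stats.linregress(x, resp)
            slope, intercept = float(res.slope), float(res.intercept)
        pred = intercept + slope * x
        ss_res = float(np.sum((resp - pred) ** 2))
        ss_tot = float(np.sum((resp - resp.mean()) ** 2))
        if ss_tot == 0.0:
            if ss_res > 1e-9 * max(1.0, float(np.abs(resp).max())):
                raise FitError("zero response variance with nonzero residuals")
            r2 = 1.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        denom = n if self.rmse_denominator == "n" else n - 2
        rmse = math.sqrt(ss_res / denom)
        mean_resp = float(resp.mean())
        if mean_resp == 0.0:
            raise FitError("relative RMSE undefined: mean response is zero")

        self.slope_ = slope
        self.intercept_ = intercept
        self.r_squared_ = float(r2)
        self.rmse_ = float(rmse)
        self.rrmse_percent_ = 100.0 * rmse / mean_resp
        self.n_points_ = int(n)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "slope_"):
            raise FitError("estimator is not fitted")

    def predict(self, X) -> np.ndarray:
        """Expected response at the given concentrations."""
        self._check_fitted()
        return self.intercept_ + self.slope_ * self._as_1d(X)

    def inverse_predict(self, y):
        """Concentration(s) corresponding to measured response(s)."""
        self._check_fitted()
        return inverse_predict(self.to_curve(), y)

    def to_curve(self) -> CalibrationCurve:
        self._check_fitted()
        return CalibrationCurve(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            rmse=self.rmse_,
            rrmse_percent=self.rrmse_percent_,
            n_points=self.n_points_,
            channel_or_mode=self.channel,
        )

    @classmethod
    def from_curve(cls, curve: CalibrationCurve) -> "LinearCalibrator":
        est = cls(channel=curve.channel_or_mode)
        est.slope_ = curve.slope
        est.intercept_ = curve.intercept
        est.r_squared_ = curve.r_squared
        est.rmse_ = curve.rmse
        est.rrmse_percent_ = curve.rrmse_percent
        est.n_points_ = curve.n_points
        return est


def fit_linear(
    concentrations: Sequence[float],
    responses: Sequence[float],
    channel_or_mode: str = "B",
    rmse_denominator: str = "n",
) -> CalibrationCurve:
    """OLS standard curve of response on concentration (functional wrapper)."""
    est = LinearCalibrator(channel=channel_or_mode, rmse_denominator=rmse_denominator)
    return est.fit(concentrations, responses).to_curve()


def inverse_predict(curve: CalibrationCurve, response):
    """Concentration from measured response: (response - intercept) / slope.

    May be negative for responses below the blank; callers flag rather than
    clamp such values.
    """
    if curve.slope == 0:
        raise FitError("cannot invert a curve with zero slope")
    resp = np.asarray(response, dtype=float)
    out = (resp - curve.intercept) / curve.slope
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LevelDecision:
    """Per-level record of the blank-comparison test."""

    concentration: float
    statistic: float
    p_value: float
    significant: bool


@dataclass
class LodResult:
    """Detection/quantification limits with the per-level decision record.

    ``censored`` marks an LOD at the lowest tested level when every level
    was distinguishable (the true LOD may be lower: report as "<=").
    """

    lod: float
    loq: float
    censored: bool
    decisions: list[LevelDecision] = field(default_factory=list)


def loq_from_lod(lod: float) -> float:
    """Limit of quantification, defined as exactly three times the LOD."""
    if lod <= 0:
        raise SchemaError(f"LOD must be > 0, got {lod}")
    return 3.0 * lod


def estimate_lod(
    blank_responses: Sequence[float],
    level_responses: Mapping[float, Sequence[float]],
    alpha: float = 0.05,
    slope_sign: float = 1.0,
    alternative: str | None = None,
) -> LodResult:
    """Walk a two-fold (or any strictly decreasing) series down to the LOD.

    Parameters
    ----------
    blank_responses : replicate responses of the 0 μg/mL blank (>= 2).
    level_responses : concentration -> replicate responses (>= 2 each);
        evaluated in decreasing concentration order.
    alpha : one-sided significance level of the Welch t-test.
    slope_sign : sign of the calibration slope; positive means signal
        increases with concentration (test direction "greater").
    alternative : override the test direction explicitly if given.
    """
    blanks = np.asarray(blank_responses, dtype=float)
    if blanks.size < 2:
        raise SchemaError("need >= 2 blank replicates")
    if not level_responses:
        raise SchemaError("need at least one dilution level")
    if not (0 < alpha < 1):
        raise SchemaError(f"alpha must be in (0, 1), got {alpha}")
    concs = sorted(level_responses, reverse=True)
    if len(set(concs)) != len(concs):
        raise SchemaError("dilution levels must be distinct")
    if alternative is None:
        alternative = "greater" if slope_sign >= 0 else "less"

    decisions: list[LevelDecision] = []
    lod: float | None = None
    chain_intact = True
    for conc in concs:
        values = np.asarray(level_responses[conc], dtype=float)
        if values.size < 2:
            raise SchemaError(f"need >= 2 replicates at {conc} μg/mL")
        with np.errstate(invalid="ignore", divide="ignore"):
            stat, p = stats.ttest_ind(values, blanks, equal_var=False, alternative=alternative)
        significant = bool(np.isfinite(p) and p < alpha)
        decisions.append(LevelDecision(float(conc), float(stat), float(p), significant))
        if chain_intact and significant:
            lod = float(conc)
        else:
            chain_intact = False

    if lod is None:
        raise UndetectableError(
            "no dilution level is statistically distinguishable from the blank"
        )
    censored = lod == concs[-1]
    return LodResult(lod=lod, loq=loq_from_lod(lod), censored=censored, decisions=decisions)


def lod_decisions_frame(result: LodResult):
    """Decision record as a DataFrame (concentration, t, p, significant)."""
    import pandas as pd

    return pd.DataFrame.from_records(
        [asdict(d) for d in result.decisions],
        columns=["concentration", "statistic", "p_value", "significant"],
    )
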