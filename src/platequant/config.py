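"""Run configuration: schema-validated defaults for the whole pipeline.

Defaults reproduce the reference assay settings: blue-channel response,
alpha = 0.05 for the detection-limit test, the standard dilution scheme
(0.1 g / 5 mL / 20->1000 μL), outlier screening off, seed 0.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import InputError, SchemaError
from .plate import DilutionScheme

_CHANNELS = ("R", "G", "B", "absorbance")
_OUTLIER = ("none", "dixon_q")
_LIGHTING = ("well_lit", "poor", "outdoor")
_RMSE = ("n", "n-2")


@dataclass(frozen=True)
class RunConfig:
    channel: str = "B"
    alpha: float = 0.05
    rmse_denominator: str = "n"
    outlier: str = "none"
    confidence: float = 0.95
    lighting: str = "well_lit"
    noise_sd: float = 1.0
    seed: int = 0
    scheme: DilutionScheme = field(default_factory=DilutionScheme)

    def __post_init__(self) -> None:
        if self.channel not in _CHANNELS:
            raise SchemaError(f"channel must be one of {_CHANNELS}, got {self.channel!r}")
        if not (0 < self.alpha < 1):
            raise SchemaError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.rmse_denominator not in _RMSE:
            raise SchemaError(f"rmse_denominator must be one of {_RMSE}")
        if self.outlier not in _OUTLIER:
            raise SchemaError(f"outlier must be one of {_OUTLIER}, got {self.outlier!r}")
        if self.confidence not in (0.90, 0.95, 0.99):
            raise SchemaError("confidence must be 0.90, 0.95 or 0.99")
        if self.lighting not in _LIGHTING:
            raise SchemaError(f"lighting must be one of {_LIGHTING}, got {self.lighting!r}")
        if self.noise_sd < 0:
            raise SchemaError("noise_sd must be >= 0")
        if not isinstance(self.seed, int):
            raise SchemaError("seed must be an integer")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["scheme"] = dataclasses.asdict(self.scheme)
        return d

    def hash(self) -> str:
        """Stable hash of the canonical configuration, for run logs."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_TOP_KEYS = {
    "channel", "alpha", "rmse_denominator", "outlier", "confidence",
    "lighting", "noise_sd", "seed", "scheme",
}
_SCHEME_KEYS = {f.name for f in dataclasses.fields(DilutionScheme)}


def config_from_mapping(payload: Mapping[str, Any]) -> RunConfig:
    """Build a validated RunConfig; unknown keys are rejected."""
    unknown = set(payload) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = dict(payload)
    scheme_payload = kwargs.pop("scheme", None)
    if scheme_payload is not None:
        if not isinstance(scheme_payload, Mapping):
            raise SchemaError("config key 'scheme' must be a mapping")
        bad = set(scheme_payload) - _SCHEME_KEYS
        if bad:
            raise SchemaError(f"unknown scheme keys: {sorted(bad)}")
        kwargs["scheme"] = DilutionScheme(**{k: float(v) for k, v in scheme_payload.items()})
    try:
        return RunConfig(**kwargs)
    except TypeError as exc:
        raise SchemaError(f"invalid config: {exc}") from exc


def load_config(path: str | Path | None, overrides: Mapping[str, Any] | None = None) -> RunConfig:
    """Load YAML/JSON config (optional) and apply CLI overrides on top."""
    payload: dict[str, Any] = {}
    if path is not None:
        try:
            text = Path(path).read_text()
        except OSError as exc:
            raise InputError(f"cannot read config {path}: {exc}") from exc
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise SchemaError(f"config {path} is not valid YAML/JSON: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise SchemaError("config root must be a mapping")
        payload.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            payload[key] = value
    return config_from_mapping(payload)
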