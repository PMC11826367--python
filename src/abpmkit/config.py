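"""Run configuration: thresholds, formula variants and analysis options.

Every clinically meaningful threshold lives here with the guideline
value as default, so sensitivity analyses need a config change rather
than a code change.  Unknown keys in a config file are rejected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import time
from pathlib import Path

import yaml

from abpmkit.recording import HTThresholds, WindowConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the end-to-end pipeline."""

    # windowing (clock hours) and measurement schedule
    day_start_hour: int = 6
    night_start_hour: int = 22
    day_interval_min: int = 20
    night_interval_min: int = 30
    strict_per_hour: bool = True
    # ambulatory hypertension thresholds, (SBP, DBP) mmHg
    ht_day: tuple[float, float] = (135.0, 85.0)
    ht_night: tuple[float, float] = (120.0, 70.0)
    ht_24h: tuple[float, float] = (130.0, 80.0)
    # formula variants
    bsa_formula: str = "mosteller"  # mosteller | dubois
    egfr_version: int = 2009  # 2009 | 2021
    arv_time_weighted: bool = False
    ppi_per_reading: bool = True
    # analysis options
    hl_groups: int = 10
    p_screen: float = 0.25
    forced_clinical: tuple[str, ...] = ()
    roc_variables: tuple[str, ...] = ("aasi", "arv_sbp", "ppi")
    candidate_predictors: tuple[str, ...] = (
        "age",
        "sex",
        "bmi",
        "smoking",
        "hba1c",
        "lvef",
        "arv_sbp",
        "aasi",
        "ppi",
    )
    seed: int = 0
    log_level: str = "info"

    def window_config(self) -> WindowConfig:
        return WindowConfig(
            day_start=time(self.day_start_hour, 0),
            night_start=time(self.night_start_hour, 0),
            day_interval_min=self.day_interval_min,
            night_interval_min=self.night_interval_min,
            strict_per_hour=self.strict_per_hour,
        )

    def thresholds(self) -> HTThresholds:
        return HTThresholds(
            day=tuple(self.ht_day), night=tuple(self.ht_night), full=tuple(self.ht_24h)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def semantic_hash(self) -> str:
        """Hash of every option that changes results (log level excluded)."""
        d = self.to_dict()
        d.pop("log_level")
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config file, rejecting unknown keys."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("ht_day", "ht_night", "ht_24h", "forced_clinical", "roc_variables", "candidate_predictors"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
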