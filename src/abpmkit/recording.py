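"""Parsing, validation and summarisation of 24-hour ABPM recordings.

An ambulatory monitor is programmed to read blood pressure every 20
minutes during the day (06:00-21:59) and every 30 minutes at night
(22:00-05:59), so a complete 24-hour recording holds 48 daytime and 16
night-time readings.  This module parses such recordings from delimited
text, applies the standard validity rules (>=70 % valid readings, >=20
valid by day with at least two per clock hour, >=7 valid by night with
at least one per hour), and derives the per-subject summary: window
means, pressure loads, nocturnal dipping, and the three indices

* ARV  — average real variability, the mean absolute difference between
  consecutive readings (mmHg);
* AASI — ambulatory arterial stiffness index, one minus the ordinary
  least-squares slope of diastolic on systolic pressure over 24 h;
* PPI  — pulse pressure index, pulse pressure as a percentage of
  systolic pressure, averaged over readings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import time, timedelta
from typing import Iterable, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BPReading",
    "WindowConfig",
    "HTThresholds",
    "ABPMRecording",
    "ValidityReport",
    "ABPMSummary",
    "HypertensionCall",
    "parse_recording",
    "validate_recording",
    "summarize_windows",
    "arv",
    "aasi",
    "ppi",
    "classify_hypertension",
]

#: Physiological plausibility bounds for a device-valid reading (mmHg).
DBP_MIN = 40.0
BP_MAX = 300.0


@dataclass(frozen=True)
class BPReading:
    """A single timestamped blood-pressure reading (mmHg)."""

    timestamp: pd.Timestamp
    sbp: float
    dbp: float
    valid: bool = True


@dataclass(frozen=True)
class WindowConfig:
    """Day/night windowing of the 24-h clock.

    Windows are half-open: a reading stamped exactly at ``day_start``
    (default 06:00) is daytime, one at ``night_start`` (22:00) is
    night-time.  ``strict_per_hour`` selects the literal per-clock-hour
    validity rule; when False, only the average-rate counts are checked.
    """

    day_start: time = time(6, 0)
    night_start: time = time(22, 0)
    day_interval_min: int = 20
    night_interval_min: int = 30
    strict_per_hour: bool = True

    def __post_init__(self) -> None:
        if self.day_interval_min <= 0 or self.night_interval_min <= 0:
            raise ValueError("measurement intervals must be positive")
        if self.day_start >= self.night_start:
            raise ValueError("day_start must precede night_start on the clock")

    def is_day(self, timestamps: pd.Series | pd.DatetimeIndex) -> np.ndarray:
        """Boolean daytime mask for clock times in [day_start, night_start)."""
        ts = pd.DatetimeIndex(timestamps)
        frac = ts.hour * 60 + ts.minute
        lo = self.day_start.hour * 60 + self.day_start.minute
        hi = self.night_start.hour * 60 + self.night_start.minute
        return np.asarray((frac >= lo) & (frac < hi))

    @property
    def day_hours(self) -> list[int]:
        return list(range(self.day_start.hour, self.night_start.hour))

    @property
    def night_hours(self) -> list[int]:
        return [h % 24 for h in range(self.night_start.hour, 24 + self.day_start.hour)]


@dataclass(frozen=True)
class HTThresholds:
    """Window-specific hypertension cut-offs (SBP, DBP in mmHg), inclusive."""

    day: tuple[float, float] = (135.0, 85.0)
    night: tuple[float, float] = (120.0, 70.0)
    full: tuple[float, float] = (130.0, 80.0)


class ABPMRecording:
    """One subject's ordered 24-h sequence of blood-pressure readings.

    Backed by a :class:`pandas.DataFrame` with columns ``timestamp``,
    ``sbp``, ``dbp``, ``valid``.  Timestamps must be strictly
    increasing and span at most 26 hours.
    """

    MAX_SPAN = timedelta(hours=26)

    def __init__(
        self,
        subject_id: str,
        readings: pd.DataFrame | Iterable[BPReading],
        window_config: WindowConfig | None = None,
    ) -> None:
        if not isinstance(readings, pd.DataFrame):
            readings = pd.DataFrame(
                [(r.timestamp, r.sbp, r.dbp, r.valid) for r in readings],
                columns=["timestamp", "sbp", "dbp", "valid"],
            )
        else:
            readings = readings.copy()
        if "valid" not in readings.columns:
            readings["valid"] = True
        readings = readings[["timestamp", "sbp", "dbp", "valid"]]
        readings["timestamp"] = pd.to_datetime(readings["timestamp"])
        readings["valid"] = readings["valid"].astype(bool)
        if len(readings) < 1:
            raise ValueError(f"recording {subject_id!r} is empty")
        diffs = readings["timestamp"].diff().dropna()
        if (diffs <= pd.Timedelta(0)).any():
            raise ValueError(f"recording {subject_id!r}: timestamps not strictly increasing")
        span = readings["timestamp"].iloc[-1] - readings["timestamp"].iloc[0]
        if span > self.MAX_SPAN:
            raise ValueError(f"recording {subject_id!r} spans {span}, more than 26 h")
        self.subject_id = str(subject_id)
        self.frame = readings.reset_index(drop=True)
        self.window_config = window_config or WindowConfig()

    def __len__(self) -> int:
        return len(self.frame)

    def __repr__(self) -> str:
        return f"ABPMRecording({self.subject_id!r}, n={len(self)})"

    @property
    def readings(self) -> list[BPReading]:
        return [
            BPReading(row.timestamp, row.sbp, row.dbp, row.valid)
            for row in self.frame.itertuples(index=False)
        ]

    def valid_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["valid"]]

    def day_mask(self) -> np.ndarray:
        return self.window_config.is_day(self.frame["timestamp"])


@dataclass(frozen=True)
class ValidityReport:
    """Outcome of the recording validity rules (counts over valid readings)."""

    fraction_valid: float
    n_day_valid: int
    n_night_valid: int
    per_hour_day_ok: bool
    per_hour_night_ok: bool
    passes: bool

    def to_dict(self) -> dict:
        return {
            "fraction_valid": self.fraction_valid,
            "n_day_valid": self.n_day_valid,
            "n_night_valid": self.n_night_valid,
            "per_hour_day_ok": self.per_hour_day_ok,
            "per_hour_night_ok": self.per_hour_night_ok,
            "passes": self.passes,
        }


@dataclass(frozen=True)
class ABPMSummary:
    """Derived per-subject ABPM parameters."""

    mean_sbp_24h: float
    mean_dbp_24h: float
    mean_sbp_day: float
    mean_dbp_day: float
    mean_sbp_night: float
    mean_dbp_night: float
    load_sbp_24h: float
    load_dbp_24h: float
    load_sbp_day: float
    load_dbp_day: float
    load_sbp_night: float
    load_dbp_night: float
    nocturnal_sbp_reduction: float
    nocturnal_dbp_reduction: float
    arv_sbp: float
    arv_dbp: float
    aasi: float
    ppi: float
    dipping_category: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass(frozen=True)
class HypertensionCall:
    """Ambulatory hypertension diagnosis with the criteria that fired."""

    hypertensive: bool
    criteria: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# parsing


def parse_recording(path, window_config: WindowConfig | None = None) -> ABPMRecording:
    """Read one subject's recording from a CSV file.

    Expected columns: ``timestamp`` (ISO-8601 local clock), ``sbp``,
    ``dbp``, optional ``valid`` (0/1, defaults to 1) and optional
    ``subject_id``.  Rows violating physiological plausibility
    (``sbp <= dbp`` or values outside [40, 300] mmHg) are flagged
    invalid with a logged warning, never silently dropped.  Non-monotone
    timestamps are an error: shuffled input indicates a corrupted file.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ValueError(f"cannot read recording file {path}: {exc}") from exc
    missing = {"timestamp", "sbp", "dbp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty recording")
    subject_id = str(df["subject_id"].iloc[0]) if "subject_id" in df.columns else str(path)
    if "valid" in df.columns:
        df["valid"] = df["valid"].astype(float).astype(bool)
    else:
        df["valid"] = True
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    implausible = df["valid"] & (
        (df["sbp"] <= df["dbp"])
        | (df["dbp"] < DBP_MIN)
        | (df["sbp"] > BP_MAX)
        | df["sbp"].isna()
        | df["dbp"].isna()
    )
    if implausible.any():
        logger.warning(
            "%s: %d physiologically implausible reading(s) flagged invalid (rows %s)",
            subject_id,
            int(implausible.sum()),
            list(df.index[implausible]),
        )
        df.loc[implausible, "valid"] = False

    return ABPMRecording(subject_id, df[["timestamp", "sbp", "dbp", "valid"]], window_config)


# ---------------------------------------------------------------------------
# validity


def validate_recording(rec: ABPMRecording) -> ValidityReport:
    """Apply the recording validity rules and return a full report.

    A recording passes when at least 70 % of programmed readings are
    valid, with >=20 valid daytime readings (at least two in every
    daytime clock hour) and >=7 valid night-time readings (at least one
    per night hour).  With ``strict_per_hour=False`` in the window
    config the per-hour criteria are waived.
    """
    cfg = rec.window_config
    frame = rec.frame
    valid = frame[frame["valid"]]
    fraction_valid = len(valid) / len(frame)
    day = cfg.is_day(valid["timestamp"])
    n_day = int(day.sum())
    n_night = int((~day).sum())

    hours_covered = set(pd.DatetimeIndex(frame["timestamp"]).hour)
    valid_hour_counts = pd.Series(pd.DatetimeIndex(valid["timestamp"]).hour).value_counts()
    # per-hour rules are only assessed for clock hours the recording reaches
    day_ok = all(
        valid_hour_counts.get(h, 0) >= 2 for h in cfg.day_hours if h in hours_covered
    )
    night_ok = all(
        valid_hour_counts.get(h, 0) >= 1 for h in cfg.night_hours if h in hours_covered
    )
    if not cfg.strict_per_hour:
        day_ok = night_ok = True

    passes = fraction_valid >= 0.70 and n_day >= 20 and n_night >= 7 and day_ok and night_ok
    return ValidityReport(
        fraction_valid=fraction_valid,
        n_day_valid=n_day,
        n_night_valid=n_night,
        per_hour_day_ok=day_ok,
        per_hour_night_ok=night_ok,
        passes=passes,
    )


# ---------------------------------------------------------------------------
# indices


def arv(
    rec: ABPMRecording,
    channel: Literal["sbp", "dbp"] = "sbp",
    time_weighted: bool = False,
) -> float:
    """Average real variability: mean |difference| of consecutive readings.

    ARV = (1/(N-1)) * sum_k |x_{k+1} - x_k| over the N valid readings in
    chronological order, unweighted by the time gap.  With
    ``time_weighted=True`` each difference is weighted by the elapsed
    time between the two readings (a common variant, off by default).
    """
    if channel not in ("sbp", "dbp"):
        raise ValueError(f"channel must be 'sbp' or 'dbp', got {channel!r}")
    valid = rec.valid_frame()
    if len(valid) < 2:
        raise ValueError(f"ARV needs >=2 valid readings, got {len(valid)}")
    x = valid[channel].to_numpy(dtype=float)
    absdiff = np.abs(np.diff(x))
    if not time_weighted:
        return float(absdiff.mean())
    w = np.diff(valid["timestamp"].to_numpy()).astype("timedelta64[s]").astype(float)
    return float(np.sum(w * absdiff) / np.sum(w))


def aasi(rec: ABPMRecording) -> float:
    """Ambulatory arterial stiffness index: 1 - OLS slope of DBP on SBP.

    The slope is the ordinary least-squares regression coefficient of
    diastolic on systolic pressure over all valid 24-h readings.  Stiff
    arteries transmit systolic swings poorly to diastolic pressure, so
    a flat slope (AASI near 1) indicates stiffness.
    """
    valid = rec.valid_frame()
    if len(valid) < 3:
        raise ValueError(f"AASI needs >=3 valid readings, got {len(valid)}")
    s = valid["sbp"].to_numpy(dtype=float)
    d = valid["dbp"].to_numpy(dtype=float)
    if np.ptp(s) == 0:
        raise ValueError("AASI undefined: systolic pressure is constant")
    slope = np.polyfit(s, d, 1)[0]
    return float(1.0 - slope)


def ppi(rec: ABPMRecording, per_reading: bool = True) -> float:
    """Pulse pressure index: pulse pressure as percent of systolic pressure.

    Default is the per-reading ratio averaged over all valid readings,
    100 * mean((sbp - dbp) / sbp); ``per_reading=False`` instead takes
    the ratio of the 24-h mean pulse pressure to the 24-h mean SBP.
    """
    valid = rec.valid_frame()
    if len(valid) < 1:
        raise ValueError("PPI needs at least one valid reading")
    s = valid["sbp"].to_numpy(dtype=float)
    d = valid["dbp"].to_numpy(dtype=float)
    if per_reading:
        return float(100.0 * np.mean((s - d) / s))
    return float(100.0 * (s.mean() - d.mean()) / s.mean())


# ---------------------------------------------------------------------------
# summary


def _load(values: np.ndarray, threshold: float) -> float:
    """Pressure load: percent of readings at or above the cut-off."""
    return float(100.0 * np.mean(values >= threshold))


def _dipping_category(sbp_reduction_pct: float) -> str:
    if sbp_reduction_pct >= 20:
        return "extreme-dipper"
    if sbp_reduction_pct >= 10:
        return "dipper"
    if sbp_reduction_pct >= 0:
        return "non-dipper"
    return "reverse-dipper"


def summarize_windows(
    rec: ABPMRecording,
    thresholds: HTThresholds | None = None,
    require_valid: bool = True,
) -> ABPMSummary:
    """Compute the full per-subject ABPM summary.

    Means are arithmetic means over valid readings in each window; the
    load is the percentage of valid readings at or above the window's
    hypertension cut-off (day 135/85, night 120/70, 24-h 130/80 mmHg);
    the nocturnal reduction is 100*(day mean - night mean)/day mean,
    with dipping categorised from the systolic reduction (>=20 %
    extreme dipper, 10-20 % dipper, 0-10 % non-dipper, <0 % reverse
    dipper).  Fails if the recording does not pass validity, unless
    ``require_valid=False`` (then a warning is logged).
    """
    thresholds = thresholds or HTThresholds()
    report = validate_recording(rec)
    if not report.passes:
        if require_valid:
            raise ValueError(
                f"recording {rec.subject_id!r} fails validity rules: {report.to_dict()}"
            )
        logger.warning("summarising %r despite failed validity rules", rec.subject_id)

    valid = rec.valid_frame()
    day_mask = rec.window_config.is_day(valid["timestamp"])
    day = valid[day_mask]
    night = valid[~day_mask]
    if len(day) == 0 or len(night) == 0:
        raise ValueError(f"recording {rec.subject_id!r}: empty day or night window")

    mean_sbp_day = float(day["sbp"].mean())
    mean_dbp_day = float(day["dbp"].mean())
    mean_sbp_night = float(night["sbp"].mean())
    mean_dbp_night = float(night["dbp"].mean())

    sbp_red = 100.0 * (mean_sbp_day - mean_sbp_night) / mean_sbp_day
    dbp_red = 100.0 * (mean_dbp_day - mean_dbp_night) / mean_dbp_day

    try:
        aasi_value = aasi(rec)
    except ValueError:
        logger.warning("AASI undefined for %r (constant SBP); reporting NaN", rec.subject_id)
        aasi_value = float("nan")

    return ABPMSummary(
        mean_sbp_24h=float(valid["sbp"].mean()),
        mean_dbp_24h=float(valid["dbp"].mean()),
        mean_sbp_day=mean_sbp_day,
        mean_dbp_day=mean_dbp_day,
        mean_sbp_night=mean_sbp_night,
        mean_dbp_night=mean_dbp_night,
        load_sbp_24h=_load(valid["sbp"].to_numpy(), thresholds.full[0]),
        load_dbp_24h=_load(valid["dbp"].to_numpy(), thresholds.full[1]),
        load_sbp_day=_load(day["sbp"].to_numpy(), thresholds.day[0]),
        load_dbp_day=_load(day["dbp"].to_numpy(), thresholds.day[1]),
        load_sbp_night=_load(night["sbp"].to_numpy(), thresholds.night[0]),
        load_dbp_night=_load(night["dbp"].to_numpy(), thresholds.night[1]),
        nocturnal_sbp_reduction=float(sbp_red),
        nocturnal_dbp_reduction=float(dbp_red),
        arv_sbp=arv(rec, "sbp"),
        arv_dbp=arv(rec, "dbp"),
        aasi=aasi_value,
        ppi=ppi(rec),
        dipping_category=_dipping_category(sbp_red),
    )


def classify_hypertension(
    summary: ABPMSummary, thresholds: HTThresholds | None = None
) -> HypertensionCall:
    """Ambulatory hypertension diagnosis from window means.

    Hypertensive iff the daytime mean is at or above 135/85, the
    night-time mean at or above 120/70, or the 24-h mean at or above
    130/80 mmHg; each criterion fires if either its systolic or its
    diastolic component meets the (inclusive) cut-off.
    """
    thr = thresholds or HTThresholds()
    fired = []
    if summary.mean_sbp_day >= thr.day[0]:
        fired.append("day_sbp")
    if summary.mean_dbp_day >= thr.day[1]:
        fired.append("day_dbp")
    if summary.mean_sbp_night >= thr.night[0]:
        fired.append("night_sbp")
    if summary.mean_dbp_night >= thr.night[1]:
        fired.append("night_dbp")
    if summary.mean_sbp_24h >= thr.full[0]:
        fired.append("24h_sbp")
    if summary.mean_dbp_24h >= thr.full[1]:
        fired.append("24h_dbp")
    return HypertensionCall(hypertensive=bool(fired), criteria=tuple(fired))
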