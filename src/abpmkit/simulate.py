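"""Synthetic ABPM recordings and two-group cohort tables.

No individual-level ABPM data are distributable with this package, so
every analysis stage is exercised on simulated subjects.  The
recording generator emulates the programmed measurement schedule (20
minutes by day, 30 by night, 48 + 16 = 64 readings over 24 h) with a
two-level circadian systolic profile plus first-order autoregressive
noise, and is *calibrated*: given a target ARV and a target AASI it
solves analytically for

* the AR(1) innovation scale such that the expected mean absolute
  consecutive difference — including the two day/night level jumps —
  equals the target ARV, and
* the within-window diastolic-on-systolic slope such that the total
  24-h OLS slope (which also picks up the between-window circadian
  covariance of the day and night levels) equals 1 - target AASI.

The cohort generator draws per-subject index targets and clinical
variables from two-group location/scale models and assigns organ
damage (heart / kidney / eyes combinations) so that the rule-based
classifier recovers the group label, which makes the full pipeline
testable end to end.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from abpmkit.hmod import LVMI_CUTOFF, body_surface_area, egfr_ckd_epi, lv_mass, EchoMeasurements
from abpmkit.recording import ABPMRecording, WindowConfig

__all__ = ["RecordingSpec", "CohortSpec", "generate_recording", "generate_cohort", "write_cohort"]

_SQRT_2_OVER_PI = np.sqrt(2.0 / np.pi)


@dataclass(frozen=True)
class RecordingSpec:
    """Target parameters for one simulated 24-h recording.

    Window means in mmHg; ``target_arv`` is the systolic average real
    variability the recording should exhibit in expectation;
    ``target_aasi`` the expected ambulatory arterial stiffness index.
    ``phi`` is the per-step AR(1) coefficient of the systolic noise and
    ``dbp_noise_sd`` the residual diastolic scatter around the
    systolic-driven component (both modelling choices, not estimands).
    """

    mean_sbp_day: float = 140.8
    mean_dbp_day: float = 84.0
    mean_sbp_night: float = 129.5
    mean_dbp_night: float = 73.8
    target_arv: float = 13.0
    target_aasi: float = 0.63
    missing_fraction: float = 0.0
    seed: int = 0
    phi: float = 0.5
    dbp_noise_sd: float = 4.0
    start: datetime = datetime(2022, 6, 1, 8, 0)

    def __post_init__(self) -> None:
        if not 0.0 < self.target_aasi < 1.0:
            raise ValueError(f"target_aasi must lie in (0, 1), got {self.target_aasi}")
        if self.target_arv <= 0:
            raise ValueError(f"target_arv must be positive, got {self.target_arv}")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if not 0.0 <= self.phi < 1.0:
            raise ValueError("phi must lie in [0, 1)")
        if self.mean_sbp_day <= self.mean_dbp_day or self.mean_sbp_night <= self.mean_dbp_night:
            raise ValueError("systolic means must exceed diastolic means")


def _schedule(cfg: WindowConfig, start: datetime, density: int = 1) -> pd.DatetimeIndex:
    """Measurement timestamps for 24 h from ``start`` on the programmed grid."""
    day_lo = cfg.day_start.hour * 60 + cfg.day_start.minute
    day_hi = cfg.night_start.hour * 60 + cfg.night_start.minute
    times = []
    t = start
    end = start + timedelta(hours=24)
    while t < end:
        times.append(t)
        minute_of_day = t.hour * 60 + t.minute + t.second / 60.0
        interval = cfg.day_interval_min if day_lo <= minute_of_day < day_hi else cfg.night_interval_min
        t = t + timedelta(minutes=interval / density)
    return pd.DatetimeIndex(times)


def _folded_normal_mean(mu, sd: float):
    """E|X| for X ~ N(mu, sd²), vectorised over ``mu``."""
    mu = np.abs(np.asarray(mu, dtype=float))
    if sd == 0:
        return mu
    return sd * _SQRT_2_OVER_PI * np.exp(-(mu**2) / (2 * sd**2)) + mu * (
        1 - 2 * special.ndtr(-mu / sd)
    )


def _solve_diff_sd(level: np.ndarray, target_arv: float) -> float:
    """Scale of consecutive-difference noise achieving the target ARV.

    The expected ARV is the average over gaps of E|jump + d| with
    d ~ N(0, s²) and ``jump`` the deterministic level change at that
    gap; solved for s by root finding.  Infeasible when the level jumps
    alone already exceed the target.
    """
    jumps = np.diff(level)
    floor = np.mean(np.abs(jumps))
    if target_arv <= floor:
        raise ValueError(
            f"target_arv {target_arv} infeasible: circadian level jumps alone give {floor:.3f}"
        )

    def f(s: float) -> float:
        return float(np.mean(_folded_normal_mean(jumps, s))) - target_arv

    hi = target_arv / _SQRT_2_OVER_PI * 2 + 1.0
    while f(hi) < 0:
        hi *= 2
    return float(optimize.brentq(f, 1e-9, hi, xtol=1e-10))


def generate_recording(
    spec: RecordingSpec,
    subject_id: str = "sim",
    window_config: WindowConfig | None = None,
    density: int = 1,
) -> ABPMRecording:
    """Simulate one calibrated 24-h ABPM recording.

    Systolic pressure is a day/night two-level profile plus stationary
    AR(1) noise whose innovation scale is solved so the expected ARV
    equals ``spec.target_arv``; diastolic pressure tracks the systolic
    noise with a within-window slope solved so the expected 24-h OLS
    slope of DBP on SBP equals ``1 - spec.target_aasi``.  Readings are
    then removed independently with probability ``missing_fraction``.
    ``density`` multiplies the sampling rate (for convergence studies);
    the calibration is re-solved on the densified schedule.  Output is
    deterministic given ``spec.seed``.
    """
    cfg = window_config or WindowConfig()
    rng = np.random.default_rng(spec.seed)
    times = _schedule(cfg, spec.start, density)
    n = len(times)
    day = cfg.is_day(times)

    level_s = np.where(day, spec.mean_sbp_day, spec.mean_sbp_night)
    level_d = np.where(day, spec.mean_dbp_day, spec.mean_dbp_night)

    # ARV calibration: s is the sd of consecutive noise differences.
    s = _solve_diff_sd(level_s, spec.target_arv)
    phi = spec.phi
    sigma = s * np.sqrt((1 + phi) / 2.0)  # AR(1) innovation sd
    v_within = sigma**2 / (1 - phi**2)  # stationary noise variance

    # AASI calibration: the 24-h OLS slope decomposes into the
    # within-window slope b_w and the between-window circadian part.
    var_between_s = float(np.var(level_s))
    cov_between = float(np.mean((level_s - level_s.mean()) * (level_d - level_d.mean())))
    b_total = 1.0 - spec.target_aasi
    b_within = (b_total * (v_within + var_between_s) - cov_between) / v_within

    e = np.empty(n)
    e[0] = rng.normal(0.0, np.sqrt(v_within))
    innov = rng.normal(0.0, sigma, size=n - 1)
    for k in range(1, n):
        e[k] = phi * e[k - 1] + innov[k - 1]

    sbp = level_s + e
    dbp = level_d + b_within * e + rng.normal(0.0, spec.dbp_noise_sd, size=n)
    # keep readings physiologically ordered: pulse pressure >= 5 mmHg
    dbp = np.minimum(dbp, sbp - 5.0)

    frame = pd.DataFrame({"timestamp": times, "sbp": sbp, "dbp": dbp, "valid": True})
    if spec.missing_fraction > 0:
        keep = rng.random(n) >= spec.missing_fraction
        if keep.sum() < 3:
            keep[:3] = True
        frame = frame[keep].reset_index(drop=True)
    return ABPMRecording(subject_id, frame, cfg)


# ---------------------------------------------------------------------------
# cohort generation


#: organ-damage combinations among damaged subjects and their probabilities
#: (heart, eyes, kidney) — the mix observed in a hospital hypertension cohort.
ORGAN_COMBINATIONS: tuple[tuple[tuple[bool, bool, bool], float], ...] = (
    ((True, False, False), 19 / 39),
    ((False, True, False), 4 / 39),
    ((False, False, True), 10 / 39),
    ((True, True, False), 3 / 39),
    ((True, False, True), 2 / 39),
    ((False, True, True), 1 / 39),
)


def _lognormal_from_median_iqr(median: float, iqr: tuple[float, float]) -> tuple[float, float]:
    """(mu, sigma) of a log-normal matched to a median and (q1, q3)."""
    mu = np.log(median)
    sigma = (np.log(iqr[1]) - np.log(iqr[0])) / (2 * stats.norm.ppf(0.75))
    return mu, max(sigma, 1e-6)


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort generator settings.

    Each ``(a, b)`` tuple gives the (damaged, control) group value.
    Defaults encode the location/scale structure of a 79-patient
    hypertension cohort: identical circadian blood-pressure levels in
    the two groups, separations injected only in the three indices
    (ARV, AASI, PPI), in BMI and in the renal markers, with age, HbA1c
    and smoking null by construction.
    """

    n_hmod: int = 39
    n_control: int = 40
    seed: int = 0
    # index targets (group mean, sd)
    arv_mean: tuple[float, float] = (14.08, 11.93)
    arv_sd: tuple[float, float] = (2.49, 1.58)
    aasi_mean: tuple[float, float] = (0.69, 0.58)
    aasi_sd: tuple[float, float] = (0.12, 0.08)
    ppi_mean: tuple[float, float] = (58.54, 48.07)
    ppi_sd: tuple[float, float] = (11.34, 6.68)
    # circadian levels (same in both groups: traditional parameters null)
    sbp_day_mean: tuple[float, float] = (140.74, 140.88)
    sbp_day_sd: tuple[float, float] = (17.63, 14.39)
    sbp_night_mean: tuple[float, float] = (129.91, 129.10)
    sbp_night_sd: tuple[float, float] = (18.65, 15.36)
    # demographics / clinical
    age_mean: tuple[float, float] = (50.1, 49.7)
    age_sd: tuple[float, float] = (12.3, 11.3)
    male_prevalence: tuple[float, float] = (0.564, 0.40)
    smoking_prevalence: tuple[float, float] = (0.359, 0.325)
    bmi_mean: tuple[float, float] = (27.75, 30.04)
    bmi_sd: tuple[float, float] = (4.77, 4.24)
    hba1c_median: tuple[float, float] = (5.8, 5.7)
    hba1c_iqr: tuple[tuple[float, float], tuple[float, float]] = ((5.4, 6.1), (5.4, 6.2))
    hemoglobin_mean: tuple[float, float] = (14.57, 14.17)
    hemoglobin_sd: tuple[float, float] = (1.48, 1.6)
    acr_median: tuple[float, float] = (19.17, 9.04)
    acr_iqr: tuple[tuple[float, float], tuple[float, float]] = ((10.87, 43.07), (4.80, 13.12))
    creatinine_mean: tuple[float, float] = (0.79, 0.75)
    creatinine_sd: tuple[float, float] = (0.15, 0.14)
    missing_fraction: float = 0.02
    organ_combinations: tuple = ORGAN_COMBINATIONS

    def __post_init__(self) -> None:
        if self.n_hmod + self.n_control < 2:
            raise ValueError("cohort needs at least two subjects")
        for name in ("male_prevalence", "smoking_prevalence"):
            for p in getattr(self, name):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"{name} must lie in [0, 1]")
        probs = [p for _, p in self.organ_combinations]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("organ combination probabilities must sum to 1")

    @classmethod
    def null(cls, seed: int = 0, **overrides) -> "CohortSpec":
        """A spec with no group differences anywhere (for calibration tests)."""
        spec = cls(seed=seed)
        fields = {}
        for f in dataclasses.fields(cls):
            v = getattr(spec, f.name)
            if isinstance(v, tuple) and len(v) == 2 and not isinstance(v[0], (tuple, bool)):
                fields[f.name] = (v[1], v[1])
            elif f.name in ("hba1c_iqr", "acr_iqr"):
                fields[f.name] = (v[1], v[1])
        fields.update(overrides)
        return dataclasses.replace(spec, **fields)


def _creatinine_for_egfr(target_egfr: float, age: float, sex: str) -> float:
    """Invert the CKD-EPI equation for serum creatinine (bisection)."""
    return float(
        optimize.brentq(
            lambda c: egfr_ckd_epi(c, age, sex) - target_egfr, 0.2, 15.0, xtol=1e-6
        )
    )


def _scale_walls_to_lvmi(
    ivst: float, pwt: float, lved: float, bsa: float, bound: float, above: bool
) -> tuple[float, float]:
    """Scale wall thicknesses so the LV mass index crosses ``bound``."""
    for _ in range(60):
        echo = EchoMeasurements(lved=lved, ivst=ivst, pwt=pwt)
        lvmi = lv_mass(echo) / bsa
        if above and lvmi > bound:
            return ivst, pwt
        if not above and lvmi < bound:
            return ivst, pwt
        factor = 1.05 if above else 0.95
        ivst *= factor
        pwt *= factor
    return ivst, pwt


def _draw_subject(
    rng: np.random.Generator,
    spec: CohortSpec,
    g: int,
    organs: tuple[bool, bool, bool],
    subject_id: str,
) -> tuple[dict, RecordingSpec]:
    """One subject's clinical row and recording spec; ``g`` indexes the group."""
    heart, eyes, kidney = organs
    sex = "male" if rng.random() < spec.male_prevalence[g] else "female"
    age = float(np.clip(rng.normal(spec.age_mean[g], spec.age_sd[g]), 25, 80))
    bmi = float(np.clip(rng.normal(spec.bmi_mean[g], spec.bmi_sd[g]), 17, 45))
    height = float(rng.normal(174 if sex == "male" else 161, 6.5))
    weight = bmi * (height / 100.0) ** 2
    bsa = body_surface_area(height, weight)

    # ---- echo
    lved = float(np.clip(rng.normal(4.53, 0.40), 3.6, 5.8))
    lvef = float(np.clip(rng.normal(64.5, 4.9), 50, 78))
    wall_mu, wall_sd = ((1.20, 0.14), (1.05, 0.07))[0 if heart else 1]
    ivst = float(np.clip(rng.normal(wall_mu, wall_sd), 0.7, 1.8))
    pwt = float(np.clip(rng.normal(wall_mu - 0.08, wall_sd), 0.7, 1.8))
    cutoff = LVMI_CUTOFF[sex]
    if heart:
        # half the cardiac-damage subjects get frank LVH, all get grade I
        # impaired relaxation so the rule set recovers the assignment
        e_a = float(rng.uniform(0.55, 0.78))
        if rng.random() < 0.5:
            ivst, pwt = _scale_walls_to_lvmi(ivst, pwt, lved, bsa, cutoff * 1.02, above=True)
        e_over_e_prime = float(np.clip(rng.normal(12.5, 3.5), 4, 25))
        trv = float(np.clip(rng.normal(2.49, 0.60), 1.2, 3.6))
        septal_e = float(np.clip(rng.normal(6.2, 1.4), 3, 12))
        lateral_e = float(np.clip(rng.normal(9.0, 2.2), 4, 16))
    else:
        e_a = float(rng.uniform(0.85, 1.6))
        ivst, pwt = _scale_walls_to_lvmi(ivst, pwt, lved, bsa, cutoff * 0.97, above=False)
        e_over_e_prime = float(np.clip(rng.normal(7.0, 1.3), 4, 13.5))
        trv = float(np.clip(rng.normal(1.95, 0.45), 1.0, 2.75))
        septal_e = float(np.clip(rng.normal(7.6, 1.5), 3, 12))
        lateral_e = float(np.clip(rng.normal(11.3, 2.6), 4, 18))
    lavi = float(np.clip(rng.normal(26.5, 5.0), 15, 33.5))
    a_wave = float(np.clip(rng.normal(70, 12), 40, 110))
    dt = float(np.clip(rng.normal(212, 35), 140, 300))

    # ---- renal
    if kidney:
        if rng.random() < 0.8:  # albuminuria route
            mu, sg = _lognormal_from_median_iqr(60.0, (35.0, 110.0))
            acr = float(np.clip(rng.lognormal(mu, sg), 31.0, 600.0))
            creatinine = float(np.clip(rng.normal(spec.creatinine_mean[g], spec.creatinine_sd[g]), 0.5, 1.05))
        else:  # low eGFR route
            acr = float(np.clip(rng.lognormal(*_lognormal_from_median_iqr(spec.acr_median[g], spec.acr_iqr[g])), 1.0, 29.0))
            creatinine = _creatinine_for_egfr(float(rng.uniform(42.0, 57.0)), age, sex)
    else:
        mu, sg = _lognormal_from_median_iqr(spec.acr_median[g], spec.acr_iqr[g])
        acr = float(np.clip(rng.lognormal(mu, sg), 0.5, 29.0))
        creatinine = float(np.clip(rng.normal(spec.creatinine_mean[g], spec.creatinine_sd[g]), 0.5, 1.05))
        if egfr_ckd_epi(creatinine, age, sex) < 61.0:
            creatinine = _creatinine_for_egfr(float(rng.uniform(65.0, 90.0)), age, sex)

    # ---- recording targets
    arv_t = float(np.clip(rng.normal(spec.arv_mean[g], spec.arv_sd[g]), 4.0, 30.0))
    aasi_t = float(np.clip(rng.normal(spec.aasi_mean[g], spec.aasi_sd[g]), 0.10, 0.92))
    ppi_t = float(np.clip(rng.normal(spec.ppi_mean[g], spec.ppi_sd[g]), 25.0, 75.0))
    sbp_day = float(np.clip(rng.normal(spec.sbp_day_mean[g], spec.sbp_day_sd[g]), 100, 200))
    sbp_night = float(np.clip(rng.normal(spec.sbp_night_mean[g], spec.sbp_night_sd[g]), 90, 195))
    q = 1.0 - ppi_t / 100.0
    rec_spec = RecordingSpec(
        mean_sbp_day=sbp_day,
        mean_dbp_day=sbp_day * q,
        mean_sbp_night=sbp_night,
        mean_dbp_night=sbp_night * q,
        target_arv=arv_t,
        target_aasi=aasi_t,
        missing_fraction=spec.missing_fraction,
        seed=int(rng.integers(0, 2**31 - 1)),
    )

    row = {
        "subject_id": subject_id,
        "group": "hmod" if g == 0 else "control",
        "hmod": int(g == 0),
        "organ_heart": int(heart),
        "organ_eyes": int(eyes),
        "organ_kidney": int(kidney),
        "age": age,
        "sex": sex,
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "smoking": int(rng.random() < spec.smoking_prevalence[g]),
        "hemoglobin": float(rng.normal(spec.hemoglobin_mean[g], spec.hemoglobin_sd[g])),
        "hba1c": float(rng.lognormal(*_lognormal_from_median_iqr(spec.hba1c_median[g], spec.hba1c_iqr[g]))),
        "serum_creatinine": creatinine,
        "urine_albumin_creatinine_ratio": acr,
        "lved": lved,
        "ivst": ivst,
        "pwt": pwt,
        "lvef": lvef,
        "e_a_ratio": e_a,
        "e_wave": e_a * a_wave,
        "a_wave": a_wave,
        "septal_e_prime": septal_e,
        "lateral_e_prime": lateral_e,
        "e_over_e_prime": e_over_e_prime,
        "lavi": lavi,
        "trv": trv,
        "dt": dt,
        "fundoscopy_flag": int(eyes),
        "target_arv": arv_t,
        "target_aasi": aasi_t,
        "target_ppi": ppi_t,
    }
    return row, rec_spec


def generate_cohort(
    spec: CohortSpec, window_config: WindowConfig | None = None
) -> tuple[pd.DataFrame, dict[str, ABPMRecording]]:
    """Generate the per-subject clinical table and one recording each.

    Returns ``(cohort, recordings)`` where ``cohort`` has one row per
    subject (demographics, labs, echo, fundoscopy, true group label and
    the index targets used for calibration) and ``recordings`` maps
    subject id to its simulated :class:`ABPMRecording`.  Deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    combos = [c for c, _ in spec.organ_combinations]
    probs = [p for _, p in spec.organ_combinations]
    rows, recordings = [], {}
    for g, n, prefix in ((0, spec.n_hmod, "H"), (1, spec.n_control, "C")):
        for i in range(n):
            organs = combos[rng.choice(len(combos), p=probs)] if g == 0 else (False, False, False)
            sid = f"{prefix}{i + 1:03d}"
            row, rec_spec = _draw_subject(rng, spec, g, organs, sid)
            rows.append(row)
            recordings[sid] = generate_recording(rec_spec, sid, window_config)
    return pd.DataFrame(rows), recordings


def write_cohort(
    cohort: pd.DataFrame, recordings: dict[str, ABPMRecording], out_dir: str | Path
) -> tuple[Path, Path]:
    """Write ``cohort.csv`` and a combined ``readings.csv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.csv"
    cohort.to_csv(cohort_path, index=False)
    frames = []
    for sid, rec in recordings.items():
        f = rec.frame.copy()
        f.insert(0, "subject_id", sid)
        f["valid"] = f["valid"].astype(int)
        frames.append(f)
    readings_path = out / "readings.csv"
    pd.concat(frames, ignore_index=True).to_csv(readings_path, index=False)
    return cohort_path, readings_path
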