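"""Rule-based classification of hypertension-mediated organ damage (HMOD).

Chronic hypertension damages the heart (left-ventricular hypertrophy,
diastolic dysfunction), the kidneys (reduced glomerular filtration,
albuminuria) and the retina.  This module turns echocardiographic
measurements, laboratory values and a fundoscopy flag into per-organ
damage flags and a composite HMOD indicator:

* cardiac — LVH when the left-ventricular mass index exceeds 115 g/m²
  in men or 95 g/m² in women (concentric geometry when relative wall
  thickness exceeds 0.43), or diastolic dysfunction of any grade;
* renal — CKD-EPI eGFR below 60 mL/min/1.73 m² or a urinary
  albumin/creatinine ratio above 30 mg/g;
* retinal — hypertensive retinopathy on fundoscopy (input flag).

Left-ventricular mass uses the Devereux cube formula; body surface
area uses Mosteller by default (Du Bois selectable).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal

logger = logging.getLogger(__name__)

__all__ = [
    "EchoMeasurements",
    "Demographics",
    "LabPanel",
    "HMODStatus",
    "body_surface_area",
    "lv_mass",
    "lvmi_rwt",
    "lvh_flag",
    "diastolic_grade",
    "egfr_ckd_epi",
    "nephropathy_flag",
    "hmod_composite",
]

Sex = Literal["male", "female"]

#: LVH cut-offs for LV mass index, g/m² (strict 'exceeds').
LVMI_CUTOFF = {"male": 115.0, "female": 95.0}
RWT_CONCENTRIC = 0.43
EGFR_CUTOFF = 60.0  # mL/min/1.73 m², strict 'below'
ACR_CUTOFF = 30.0  # mg/g, strict 'exceeds'


@dataclass(frozen=True)
class EchoMeasurements:
    """Transthoracic echocardiographic measurements for one subject.

    Linear dimensions in cm, velocities in cm/s except ``trv`` (m/s),
    ``lavi`` in mL/m², ``dt`` (deceleration time, ms) carried but not
    used by any rule.  Missing values are ``None``.
    """

    lved: float | None = None
    ivst: float | None = None
    pwt: float | None = None
    lvef: float | None = None
    e_wave: float | None = None
    a_wave: float | None = None
    e_a_ratio: float | None = None
    septal_e_prime: float | None = None
    lateral_e_prime: float | None = None
    e_over_e_prime: float | None = None
    lavi: float | None = None
    trv: float | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value is not None and value < 0:
                raise ValueError(f"echo measurement {name} must be non-negative, got {value}")
        if (
            self.e_a_ratio is not None
            and self.e_wave is not None
            and self.a_wave not in (None, 0)
            and not math.isclose(self.e_a_ratio, self.e_wave / self.a_wave, rel_tol=0.05)
        ):
            raise ValueError("e_a_ratio inconsistent with e_wave / a_wave")


@dataclass(frozen=True)
class Demographics:
    """Demographic and anthropometric data for one subject."""

    age: float
    sex: Sex
    height: float | None = None  # cm
    weight: float | None = None  # kg
    bmi: float | None = None  # kg/m²
    smoking: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.bmi is not None and self.height and self.weight:
            implied = self.weight / (self.height / 100.0) ** 2
            if abs(implied - self.bmi) > 0.02 * self.bmi:
                raise ValueError(
                    f"bmi {self.bmi} inconsistent with height/weight (implies {implied:.2f})"
                )


@dataclass(frozen=True)
class LabPanel:
    """Laboratory panel; creatinine in mg/dL, ACR in mg/g."""

    serum_creatinine: float | None = None
    urine_albumin_creatinine_ratio: float | None = None
    other: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.serum_creatinine is not None and self.serum_creatinine <= 0:
            raise ValueError("serum creatinine must be positive")


@dataclass(frozen=True)
class HMODStatus:
    """Per-organ damage flags plus the composite HMOD indicator."""

    cardiac: bool | None
    cardiac_basis: str  # LVH | diastolic_dysfunction | both | none | indeterminate
    retinal: bool | None
    renal: bool | None
    renal_basis: str  # low_egfr | albuminuria | both | none | indeterminate
    hmod: bool
    diastolic_grade: str  # none | I | II | III | indeterminate

    def organ_combination(self) -> str:
        """Label like 'heart+kidney' of the organs flagged damaged."""
        parts = []
        if self.cardiac:
            parts.append("heart")
        if self.retinal:
            parts.append("eyes")
        if self.renal:
            parts.append("kidney")
        return "+".join(parts) if parts else "none"


# ---------------------------------------------------------------------------
# anthropometry and LV mass


def body_surface_area(
    height: float, weight: float, formula: Literal["mosteller", "dubois"] = "mosteller"
) -> float:
    """Body surface area in m² from height (cm) and weight (kg).

    Mosteller: sqrt(height * weight / 3600); Du Bois:
    0.007184 * height^0.725 * weight^0.425.
    """
    if height <= 0 or weight <= 0:
        raise ValueError("height and weight must be positive")
    if formula == "mosteller":
        return math.sqrt(height * weight / 3600.0)
    if formula == "dubois":
        return 0.007184 * height**0.725 * weight**0.425
    raise ValueError(f"unknown BSA formula {formula!r}")


def lv_mass(echo: EchoMeasurements) -> float:
    """Left-ventricular mass (g) by the Devereux cube formula.

    LVM = 0.8 * 1.04 * [(IVST + LVED + PWT)^3 - LVED^3] + 0.6, with the
    three linear dimensions in cm.
    """
    if echo.lved is None or echo.ivst is None or echo.pwt is None:
        raise ValueError("lv_mass requires lved, ivst and pwt")
    return 0.8 * 1.04 * ((echo.ivst + echo.lved + echo.pwt) ** 3 - echo.lved**3) + 0.6


def lvmi_rwt(
    echo: EchoMeasurements,
    demo: Demographics,
    bsa_formula: Literal["mosteller", "dubois"] = "mosteller",
) -> tuple[float, float]:
    """LV mass index (g/m²) and relative wall thickness (2*PWT/LVED)."""
    if demo.height is None or demo.weight is None:
        raise ValueError("lvmi requires height and weight for body surface area")
    bsa = body_surface_area(demo.height, demo.weight, bsa_formula)
    if echo.lved == 0:
        raise ValueError("relative wall thickness undefined for zero LVED")
    return lv_mass(echo) / bsa, 2.0 * echo.pwt / echo.lved


def lvh_flag(lvmi: float, sex: Sex, rwt: float | None = None) -> tuple[bool, str]:
    """Left-ventricular hypertrophy call and geometry.

    LVH when LVMI strictly exceeds 115 g/m² (men) or 95 g/m² (women);
    geometry is 'concentric' when RWT strictly exceeds 0.43, else
    'eccentric' for hypertrophied ventricles, 'normal' otherwise.
    """
    if sex not in LVMI_CUTOFF:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    lvh = lvmi > LVMI_CUTOFF[sex]
    concentric = rwt is not None and rwt > RWT_CONCENTRIC
    if lvh:
        geometry = "concentric" if concentric else "eccentric"
    else:
        geometry = "concentric-remodelling" if concentric else "normal"
    return lvh, geometry


# ---------------------------------------------------------------------------
# diastolic function


def diastolic_grade(echo: EchoMeasurements) -> tuple[str, dict]:
    """Grade diastolic dysfunction (none, I, II, III or indeterminate).

    Grade I (impaired relaxation): E/A < 0.8.  Grades II and III
    additionally require evidence of elevated filling pressures with an
    E/A of 0.8-2.0 (II) or >2.0 (III): at least two positive markers
    among E/e' > 14, LAVI > 34 mL/m², TRV > 2.8 m/s, septal e' < 7 cm/s
    and lateral e' < 10 cm/s — the e' velocity criteria counting only
    when at least one of the TRV/LAVI criteria is also positive.
    Returns the grade and the marker breakdown.
    """
    if echo.e_a_ratio is None:
        raise ValueError("diastolic grading requires the E/A ratio")

    markers: dict[str, bool | None] = {
        "e_over_e_prime_gt_14": None if echo.e_over_e_prime is None else echo.e_over_e_prime > 14,
        "lavi_gt_34": None if echo.lavi is None else echo.lavi > 34,
        "trv_gt_2_8": None if echo.trv is None else echo.trv > 2.8,
        "septal_e_prime_lt_7": None if echo.septal_e_prime is None else echo.septal_e_prime < 7,
        "lateral_e_prime_lt_10": (
            None if echo.lateral_e_prime is None else echo.lateral_e_prime < 10
        ),
    }
    core = ("e_over_e_prime_gt_14", "lavi_gt_34", "trv_gt_2_8")
    eprime = ("septal_e_prime_lt_7", "lateral_e_prime_lt_10")
    atrial_positive = bool(markers["lavi_gt_34"]) or bool(markers["trv_gt_2_8"])
    atrial_possible = atrial_positive or any(markers[k] is None for k in ("lavi_gt_34", "trv_gt_2_8"))
    n_positive = sum(bool(markers[k]) for k in core)
    if atrial_positive:
        # e' velocities only count in combination with elevated TRV/LAVI
        n_positive += sum(bool(markers[k]) for k in eprime)
    breakdown = {"markers": markers, "n_positive": n_positive}

    if echo.e_a_ratio < 0.8:
        return "I", breakdown
    if n_positive >= 2:
        return ("II" if echo.e_a_ratio <= 2.0 else "III"), breakdown
    # could missing markers still raise the count to two?
    max_possible = sum(markers[k] is not False for k in core)
    if atrial_possible:
        max_possible += sum(markers[k] is not False for k in eprime)
    if max_possible >= 2 and any(v is None for v in markers.values()):
        return "indeterminate", breakdown
    return "none", breakdown


# ---------------------------------------------------------------------------
# renal function


def egfr_ckd_epi(
    creatinine: float, age: float, sex: Sex, version: Literal[2009, 2021] = 2009
) -> float:
    """Estimated GFR (mL/min/1.73 m²) by the CKD-EPI creatinine equation.

    Default is the 2009 equation without the race coefficient:
    141 * min(Scr/κ, 1)^α * max(Scr/κ, 1)^-1.209 * 0.993^age * 1.018 [female],
    with κ = 0.7 (F) / 0.9 (M) and α = -0.329 (F) / -0.411 (M).  The
    2021 race-free refit is selectable.
    """
    if creatinine <= 0 or age <= 0:
        raise ValueError("creatinine and age must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    kappa = 0.7 if sex == "female" else 0.9
    ratio = creatinine / kappa
    if version == 2009:
        alpha = -0.329 if sex == "female" else -0.411
        egfr = 141.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.209 * 0.993**age
        if sex == "female":
            egfr *= 1.018
    elif version == 2021:
        alpha = -0.241 if sex == "female" else -0.302
        egfr = 142.0 * min(ratio, 1.0) ** alpha * max(ratio, 1.0) ** -1.200 * 0.9938**age
        if sex == "female":
            egfr *= 1.012
    else:
        raise ValueError(f"unknown CKD-EPI version {version!r}")
    return float(egfr)


def nephropathy_flag(
    egfr: float | None = None, acr: float | None = None
) -> tuple[bool, str]:
    """Hypertensive nephropathy: eGFR < 60 mL/min/1.73 m² or ACR > 30 mg/g."""
    if egfr is None and acr is None:
        raise ValueError("nephropathy_flag needs at least one of egfr, acr")
    low_egfr = egfr is not None and egfr < EGFR_CUTOFF
    albuminuria = acr is not None and acr > ACR_CUTOFF
    if low_egfr and albuminuria:
        basis = "both"
    elif low_egfr:
        basis = "low_egfr"
    elif albuminuria:
        basis = "albuminuria"
    else:
        basis = "none"
    return low_egfr or albuminuria, basis


# ---------------------------------------------------------------------------
# composite


def hmod_composite(
    echo: EchoMeasurements | None,
    demo: Demographics,
    labs: LabPanel | None,
    fundoscopy_flag: bool | None,
    bsa_formula: Literal["mosteller", "dubois"] = "mosteller",
    egfr_version: Literal[2009, 2021] = 2009,
) -> HMODStatus:
    """Combine the per-organ rules into one HMOD status.

    Cardiac damage is LVH or diastolic dysfunction of any grade; renal
    damage follows :func:`nephropathy_flag`; retinal damage is the
    fundoscopy flag.  A missing organ evaluates to indeterminate and is
    excluded from the composite with a logged warning; the composite is
    true when any evaluable organ is damaged.
    """
    cardiac: bool | None = None
    cardiac_basis = "indeterminate"
    grade = "indeterminate"
    if echo is not None:
        lvh: bool | None = None
        try:
            lvmi, rwt = lvmi_rwt(echo, demo, bsa_formula)
            lvh, _ = lvh_flag(lvmi, demo.sex, rwt)
        except ValueError:
            logger.warning("LVH indeterminate for this subject (missing echo dimensions)")
        try:
            grade, _ = diastolic_grade(echo)
        except ValueError:
            logger.warning("diastolic grade indeterminate (missing E/A ratio)")
            grade = "indeterminate"
        dd = grade in ("I", "II", "III")
        if lvh is None and grade == "indeterminate":
            cardiac = None
        else:
            cardiac = bool(lvh) or dd
            if lvh and dd:
                cardiac_basis = "both"
            elif lvh:
                cardiac_basis = "LVH"
            elif dd:
                cardiac_basis = "diastolic_dysfunction"
            else:
                cardiac_basis = "none"

    renal: bool | None = None
    renal_basis = "indeterminate"
    if labs is not None and (
        labs.serum_creatinine is not None or labs.urine_albumin_creatinine_ratio is not None
    ):
        egfr = (
            egfr_ckd_epi(labs.serum_creatinine, demo.age, demo.sex, egfr_version)
            if labs.serum_creatinine is not None
            else None
        )
        renal, renal_basis = nephropathy_flag(egfr, labs.urine_albumin_creatinine_ratio)

    retinal = fundoscopy_flag

    organs = [cardiac, retinal, renal]
    if all(o is None for o in organs):
        raise ValueError("all organ assessments indeterminate; HMOD undefined")
    if any(o is None for o in organs):
        logger.warning("HMOD composite computed over a subset of organs (missing inputs)")

    return HMODStatus(
        cardiac=cardiac,
        cardiac_basis=cardiac_basis,
        retinal=retinal,
        renal=renal,
        renal_basis=renal_basis,
        hmod=any(bool(o) for o in organs),
        diastolic_grade=grade,
    )
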