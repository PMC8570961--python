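"""MELD/MELD-Na scoring and EF-Clif organ-failure grading.

Turns a raw lab panel (bilirubin, creatinine, INR, sodium plus organ-support
flags and encephalopathy grade) into

* the UNOS allocation scores MELD and MELD-Na (integers 6-40), and
* the six EF-Clif organ-failure flags with the derived ACLF grade 0-3.

Thresholds: liver failure bilirubin >= 12 mg/dl, kidney failure creatinine
>= 2.0 mg/dl or renal replacement therapy, cerebral failure hepatic
encephalopathy grade 3-4, coagulation failure INR >= 2.5; mechanical
ventilation stands in for respiratory failure and life-support dependency for
circulatory failure (the registry records no PaO2/FiO2 or vasopressor data).
All thresholds are inclusive.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InvalidLabError(ValueError):
    """A lab value outside its physically meaningful domain."""


class MissingDataError(ValueError):
    """A required lab field is absent/NaN."""


class InconsistentProfileError(ValueError):
    """An OrganFailureProfile whose counts contradict its flags."""


# --- MELD scoring constants (UNOS dialect in force for allocation 2016-2019).
# Isolated here so a different dialect (e.g. MELD 3.0) could be swapped in.
MELD_CONFIG = {
    "coef_creatinine": 9.57,
    "coef_bilirubin": 3.78,
    "coef_inr": 11.20,
    "constant": 6.43,
    "lab_floor": 1.0,
    "creatinine_cap": 4.0,
    "sodium_lo": 125.0,
    "sodium_hi": 137.0,
    "na_coef": 1.32,
    "na_interaction": 0.033,
    "meld_na_threshold": 11,
    "score_min": 6,
    "score_max": 40,
}


@dataclass(frozen=True)
class LabMeasurement:
    """One timed lab panel for a waitlist candidate."""

    patient_id: str
    t: float  # days since first active listing
    bilirubin: float  # mg/dl
    creatinine: float  # mg/dl
    inr: float
    sodium: float  # mmol/L
    dialysis: bool = False  # renal replacement therapy
    he_grade: int = 0  # hepatic encephalopathy, West-Haven 0-4
    mech_vent: bool = False
    circ_support: bool = False  # life-support / vasopressor surrogate

    def __post_init__(self):
        for name in ("bilirubin", "creatinine", "inr", "sodium"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise MissingDataError(f"{name} is missing for patient {self.patient_id}")
        if self.bilirubin <= 0 or self.creatinine <= 0 or self.inr <= 0 or self.sodium <= 0:
            raise InvalidLabError(
                f"non-positive lab value for patient {self.patient_id}: "
                f"bilirubin={self.bilirubin}, creatinine={self.creatinine}, "
                f"inr={self.inr}, sodium={self.sodium}"
            )
        if self.t < 0:
            raise InvalidLabError(f"negative measurement time t={self.t}")
        if self.he_grade not in (0, 1, 2, 3, 4):
            raise InvalidLabError(f"he_grade must be 0-4, got {self.he_grade}")


@dataclass(frozen=True)
class MeldScore:
    meld: int
    meld_na: int
    components: dict = field(default_factory=dict)


@dataclass(frozen=True)
class OrganFailureProfile:
    liver_f: bool
    kidney_f: bool
    brain_f: bool
    coag_f: bool
    circ_f: bool
    resp_f: bool
    kidney_dysfunction: bool
    brain_dysfunction: bool
    n_failures: int
    aclf_grade: int


def compute_meld_na(lab: LabMeasurement, config: dict = MELD_CONFIG) -> MeldScore:
    """UNOS-standard MELD and MELD-Na after input clamping.

    Labs are floored at 1.0; creatinine capped at 4.0 and set to 4.0 on
    dialysis; sodium clamped to [125, 137].  The sodium correction
    ``MELD + 1.32*(137-Na) - 0.033*MELD*(137-Na)`` applies only when
    MELD > 11.  Both scores round to integers in [6, 40].  Deterministic.
    """
    c = config
    bili = max(lab.bilirubin, c["lab_floor"])
    creat = max(lab.creatinine, c["lab_floor"])
    if lab.dialysis:
        creat = c["creatinine_cap"]
    creat = min(creat, c["creatinine_cap"])
    inr = max(lab.inr, c["lab_floor"])
    na = min(max(lab.sodium, c["sodium_lo"]), c["sodium_hi"])

    raw = (c["coef_creatinine"] * math.log(creat)
           + c["coef_bilirubin"] * math.log(bili)
           + c["coef_inr"] * math.log(inr)
           + c["constant"])
    meld = int(np.clip(round(raw), c["score_min"], c["score_max"]))

    if meld > c["meld_na_threshold"]:
        dna = c["sodium_hi"] - na
        raw_na = meld + c["na_coef"] * dna - c["na_interaction"] * meld * dna
        meld_na = int(np.clip(round(raw_na), c["score_min"], c["score_max"]))
    else:
        meld_na = meld

    return MeldScore(meld=meld, meld_na=meld_na,
                     components={"bilirubin": bili, "creatinine": creat,
                                 "inr": inr, "sodium": na})


def flag_organ_failures(lab: LabMeasurement) -> OrganFailureProfile:
    """EF-Clif organ-failure and dysfunction flags from one lab panel.

    Dysfunction bands (used by the grade-1 rule): kidney dysfunction is
    creatinine 1.5-1.9 mg/dl without kidney failure; brain dysfunction is
    encephalopathy grade 1-2.
    """
    liver_f = lab.bilirubin >= 12.0
    kidney_f = lab.creatinine >= 2.0 or bool(lab.dialysis)
    brain_f = lab.he_grade >= 3
    coag_f = lab.inr >= 2.5
    circ_f = bool(lab.circ_support)
    resp_f = bool(lab.mech_vent)
    kidney_dys = (not kidney_f) and 1.5 <= lab.creatinine < 2.0
    brain_dys = lab.he_grade in (1, 2)
    flags = (liver_f, kidney_f, brain_f, coag_f, circ_f, resp_f)
    n_fail = int(sum(flags))
    profile = OrganFailureProfile(
        liver_f=liver_f, kidney_f=kidney_f, brain_f=brain_f, coag_f=coag_f,
        circ_f=circ_f, resp_f=resp_f, kidney_dysfunction=kidney_dys,
        brain_dysfunction=brain_dys, n_failures=n_fail,
        aclf_grade=0,
    )
    return OrganFailureProfile(**{**profile.__dict__, "aclf_grade": grade_aclf(profile)})


def grade_aclf(profile: OrganFailureProfile) -> int:
    """ACLF grade 0-3 from an organ-failure profile (EF-Clif rules).

    Grade 1: single kidney failure, or a single non-kidney failure
    accompanied by kidney and/or brain dysfunction.  Grade 2: exactly two
    failures.  Grade 3: three or more.  Everything else is grade 0.
    """
    flags = (profile.liver_f, profile.kidney_f, profile.brain_f,
             profile.coag_f, profile.circ_f, profile.resp_f)
    n = int(sum(flags))
    if profile.n_failures != n:
        raise InconsistentProfileError(
            f"n_failures={profile.n_failures} but {n} failure flags are set")
    if n >= 3:
        return 3
    if n == 2:
        return 2
    if n == 1:
        if profile.kidney_f:
            return 1
        if profile.kidney_dysfunction or profile.brain_dysfunction:
            return 1
    return 0


# --- tabular interface -----------------------------------------------------

LAB_COLUMNS = ["patient_id", "t", "bilirubin", "creatinine", "inr", "sodium",
               "dialysis", "he_grade", "mech_vent", "circ_support"]

_FLAG_COLS = ["liver_f", "kidney_f", "brain_f", "coag_f", "circ_f", "resp_f"]


def read_longitudinal_csv(path) -> pd.DataFrame:
    """Read a longitudinal lab table; `t` may be day offsets or ISO dates.

    When `t` holds dates, each patient's times become days since their first
    measurement.
    """
    df = pd.read_csv(path)
    missing = [c for c in LAB_COLUMNS if c not in df.columns]
    if missing:
        raise MissingDataError(f"longitudinal table lacks columns: {missing}")
    t = pd.to_numeric(df["t"], errors="coerce")
    if t.isna().any():
        dates = pd.to_datetime(df["t"], errors="raise")
        first = dates.groupby(df["patient_id"]).transform("min")
        t = (dates - first).dt.total_seconds() / 86400.0
    df = df.copy()
    df["t"] = t.astype(float)
    for col in ("dialysis", "mech_vent", "circ_support"):
        df[col] = df[col].fillna(False).astype(bool)
    return df


def score_table(labs: pd.DataFrame) -> pd.DataFrame:
    """Append meld, meld_na, the six failure flags and aclf_grade per row."""
    rows = []
    for rec in labs.to_dict("records"):
        lab = LabMeasurement(
            patient_id=str(rec["patient_id"]), t=float(rec["t"]),
            bilirubin=float(rec["bilirubin"]), creatinine=float(rec["creatinine"]),
            inr=float(rec["inr"]), sodium=float(rec["sodium"]),
            dialysis=bool(rec.get("dialysis", False)),
            he_grade=int(rec.get("he_grade", 0)),
            mech_vent=bool(rec.get("mech_vent", False)),
            circ_support=bool(rec.get("circ_support", False)),
        )
        score = compute_meld_na(lab)
        prof = flag_organ_failures(lab)
        rows.append({"meld": score.meld, "meld_na": score.meld_na,
                     **{c: getattr(prof, c) for c in _FLAG_COLS},
                     "n_failures": prof.n_failures, "aclf_grade": prof.aclf_grade})
    return pd.concat([labs.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


def write_scored_csv(labs: pd.DataFrame, path) -> None:
    score_table(labs).to_csv(path, index=False)


def labs_for_target_meld(meld: int, config: dict = MELD_CONFIG) -> dict:
    """Crude back-solver: a plausible lab panel whose MELD is ~the target.

    Holds creatinine and INR at mid-range values and solves the bilirubin
    term; intended only for demo data, not for simulating realistic lab
    panels (which the generator deliberately does not attempt).
    """
    c = config
    x = max(float(meld) - c["constant"], 0.0)
    # spread the required log-score over the three labs on a common scale
    # s in [0,1]: creatinine, INR up to 4, bilirubin up to 50
    denom = ((c["coef_creatinine"] + c["coef_inr"]) * math.log(4.0)
             + c["coef_bilirubin"] * math.log(50.0))
    s = min(x / denom, 1.0)
    creat = min(4.0 ** s, c["creatinine_cap"])
    inr = 4.0 ** s
    bili = 50.0 ** s
    return {"bilirubin": round(bili, 2), "creatinine": round(creat, 2),
            "inr": round(inr, 2), "sodium": 137.0, "dialysis": False}
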