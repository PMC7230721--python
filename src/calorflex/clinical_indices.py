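"""Anthropometric, blood-pressure, glycemic and lipid indices plus the
four-way metabolic phenotype.

Unit conventions follow the clinical reporting of the inputs: glucose in
mg/dL, insulin in UI/mL (uU/mL), lipids in mg/dL, pressures in mm Hg,
masses in kg, height in m. HOMA converts glucose to mmol/L (x 0.0555);
the insulin-sensitivity check index uses base-10 logarithms on the
reported units. Missing inputs propagate as NaN / unclassified so each
downstream analysis can use pairwise-complete rows.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from calorflex.errors import DomainError

MG_DL_TO_MMOL_L_GLUCOSE = 0.0555

#: Metabolically-unhealthy criteria thresholds.
TG_THRESHOLD = 150.0  # >= , mg/dL
HDL_THRESHOLD = {"male": 40.0, "female": 50.0}  # < , mg/dL
SBP_THRESHOLD = 130.0  # >= , mm Hg
DBP_THRESHOLD = 85.0  # >= , mm Hg
GLUCOSE_THRESHOLD = 100.0  # > , mg/dL

BMI_NORMAL_LO = 18.5  # strict lower bound: below or equal -> unclassified
BMI_OBESE = 25.0  # inclusive overweight-obese bound

PHENOTYPES = ("MHNW", "MUNW", "MHOO", "MUOO")


def mean_blood_pressure(sbp: float, dbp: float) -> float:
    """Arithmetic mean of systolic and diastolic pressure, mm Hg.

    Deliberately (SBP + DBP) / 2, not the (SBP + 2 DBP) / 3 MAP formula.
    """
    if not (sbp > dbp > 0):
        raise DomainError(f"need sbp > dbp > 0, got sbp={sbp}, dbp={dbp}")
    return (sbp + dbp) / 2.0


def homa_ir(glucose_mg_dl: float, insulin_ui_ml: float) -> float:
    """Insulin-resistance index: insulin x glucose (mmol/L) / 22.5."""
    if glucose_mg_dl <= 0 or insulin_ui_ml <= 0:
        raise DomainError("glucose and insulin must be > 0")
    return insulin_ui_ml * (glucose_mg_dl * MG_DL_TO_MMOL_L_GLUCOSE) / 22.5


def quicki(glucose_mg_dl: float, insulin_ui_ml: float) -> float:
    """Insulin-sensitivity check index: 1 / (log10 insulin + log10 glucose)."""
    if glucose_mg_dl <= 0 or insulin_ui_ml <= 0:
        raise DomainError("glucose and insulin must be > 0")
    denom = math.log10(insulin_ui_ml) + math.log10(glucose_mg_dl)
    if denom == 0:
        raise DomainError("log10(insulin) + log10(glucose) must be nonzero")
    return 1.0 / denom


def lipid_ratios(
    tc: float, hdl: float, ldl: float, tg: float
) -> tuple[float, float]:
    """(LDL/HDL, TG/HDL); total cholesterol accepted for signature symmetry."""
    if hdl <= 0:
        raise DomainError(f"hdl must be > 0, got {hdl}")
    return ldl / hdl, tg / hdl


def classify_phenotype(
    bmi: float,
    tg: float,
    hdl: float,
    sex: str,
    sbp: float,
    dbp: float,
    glucose: float,
) -> str | None:
    """Four-way metabolic phenotype, or ``None`` when unclassifiable.

    Unhealthy iff at least one criterion is met: TG >= 150 mg/dL,
    HDL < 40 (men) / 50 (women) mg/dL, SBP >= 130 or DBP >= 85 mm Hg,
    glycemia > 100 mg/dL (strict). Normal weight is 18.5 < BMI < 25,
    overweight-obese BMI >= 25; BMI <= 18.5 or any missing input returns
    ``None``.
    """
    inputs = (bmi, tg, hdl, sbp, dbp, glucose)
    if any(x is None or (isinstance(x, float) and math.isnan(x)) for x in inputs):
        return None
    if sex not in HDL_THRESHOLD:
        return None
    if bmi <= BMI_NORMAL_LO:
        return None
    unhealthy = (
        tg >= TG_THRESHOLD
        or hdl < HDL_THRESHOLD[sex]
        or sbp >= SBP_THRESHOLD
        or dbp >= DBP_THRESHOLD
        or glucose > GLUCOSE_THRESHOLD
    )
    obese = bmi >= BMI_OBESE
    if obese:
        return "MUOO" if unhealthy else "MHOO"
    return "MUNW" if unhealthy else "MHNW"


def derive_indices(participants: pd.DataFrame) -> pd.DataFrame:
    """Append all derived index columns and the phenotype label.

    Expects the raw participant columns (weight, height, lean_mass,
    fat_mass, sbp, dbp, glucose, insulin, tc, hdl, ldl, tg); any missing
    source column simply yields missing derived values.
    """
    df = participants.copy()

    def col(name: str) -> pd.Series:
        return df[name] if name in df else pd.Series(np.nan, index=df.index)

    height2 = col("height") ** 2
    df["bmi"] = col("weight") / height2
    df["lean_mass_index"] = col("lean_mass") / height2
    df["fat_mass_index"] = col("fat_mass") / height2

    sbp, dbp = col("sbp"), col("dbp")
    df["mean_bp"] = (sbp + dbp) / 2.0
    df.loc[~(sbp > dbp), "mean_bp"] = np.nan

    glucose, insulin = col("glucose"), col("insulin")
    ok = (glucose > 0) & (insulin > 0)
    df["homa"] = np.where(
        ok, insulin * (glucose * MG_DL_TO_MMOL_L_GLUCOSE) / 22.5, np.nan
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        df["quicki"] = np.where(
            ok, 1.0 / (np.log10(insulin) + np.log10(glucose)), np.nan
        )
    df["insulin_glucose_ratio"] = np.where(ok, insulin / glucose, np.nan)

    hdl = col("hdl")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["ldl_hdl_ratio"] = np.where(hdl > 0, col("ldl") / hdl, np.nan)
        df["tg_hdl_ratio"] = np.where(hdl > 0, col("tg") / hdl, np.nan)

    df["phenotype"] = [
        classify_phenotype(
            bmi=row.get("bmi", np.nan),
            tg=row.get("tg", np.nan),
            hdl=row.get("hdl", np.nan),
            sex=row.get("sex", ""),
            sbp=row.get("sbp", np.nan),
            dbp=row.get("dbp", np.nan),
            glucose=row.get("glucose", np.nan),
        )
        for row in df.to_dict("records")
    ]
    return df
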