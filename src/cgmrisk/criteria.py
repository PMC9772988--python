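"""Deterministic clinical classification rules.

ADA diabetes diagnosis (FPG >= 126 mg/dL or HbA1c >= 6.5%, confirmed by a
second abnormal sample unless hyperglycaemia is unequivocal), incident-T2D
ascertainment over follow-up (labs or a physician record), ATP-III
metabolic syndrome (>= 3 of 5 components with the printed sex-specific
cut-offs), the HOMA-IR insulin-resistance index, and the NGSP -> IFCC
HbA1c unit conversion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

__all__ = [
    "MetabolicFlags",
    "ada_diabetes",
    "incident_t2d",
    "homa_ir",
    "hba1c_ngsp_to_ifcc",
    "hba1c_ifcc_to_ngsp",
    "fpg_mgdl_to_mmol",
    "metabolic_syndrome",
    "annotate_cohort",
]

FPG_DIABETES_MGDL = 126.0
HBA1C_DIABETES_PCT = 6.5
#: mg/dL per mmol/L of glucose (molar mass convention).
MGDL_PER_MMOL = 18.0
# NGSP -> IFCC master equation constants.
_IFCC_OFFSET = 2.15
_IFCC_SLOPE = 10.929


@dataclass(frozen=True)
class MetabolicFlags:
    """ATP-III component flags; syndrome requires at least three."""

    abdominal_obesity: bool
    hypertriglyceridaemia: bool
    low_hdl: bool
    high_bp: bool
    hyperglycaemia: bool

    @property
    def n_components(self) -> int:
        return sum(
            (
                self.abdominal_obesity,
                self.hypertriglyceridaemia,
                self.low_hdl,
                self.high_bp,
                self.hyperglycaemia,
            )
        )

    @property
    def metabolic_syndrome(self) -> bool:
        return self.n_components >= 3


def ada_diabetes(
    fpg: float | None = None,
    hba1c: float | None = None,
    second_sample_abnormal: bool = False,
    unequivocal_hyperglycaemia: bool = False,
) -> bool:
    """ADA diagnosis: threshold met AND confirmed.

    Thresholds are FPG >= 126 mg/dL or HbA1c >= 6.5% (NGSP).  In the
    absence of unequivocal hyperglycaemia a single abnormal result is not
    diagnostic; a second abnormal sample is required.
    """
    if fpg is None and hba1c is None:
        raise ValueError("at least one of fpg or hba1c must be provided")
    for name, value in (("fpg", fpg), ("hba1c", hba1c)):
        if value is not None and value < 0:
            raise ValueError(f"{name} must be nonnegative, got {value}")
    threshold = (fpg is not None and fpg >= FPG_DIABETES_MGDL) or (
        hba1c is not None and hba1c >= HBA1C_DIABETES_PCT
    )
    return bool(threshold and (unequivocal_hyperglycaemia or second_sample_abnormal))


def incident_t2d(
    baseline,
    followup_fpg: float | None = None,
    followup_hba1c: float | None = None,
    second_sample_abnormal: bool = False,
    physician_record_flag: bool = False,
    unequivocal_hyperglycaemia: bool = False,
) -> bool:
    """Incident diabetes over follow-up: ADA-positive labs or a physician
    record of diabetes.  ``baseline`` must be non-diabetic (below both
    diagnostic thresholds); a baseline at or above threshold raises,
    since such subjects are excluded at enrolment."""
    b_fpg = _get(baseline, "fpg")
    b_hba1c = _get(baseline, "hba1c")
    if (b_fpg is not None and b_fpg >= FPG_DIABETES_MGDL) or (
        b_hba1c is not None and b_hba1c >= HBA1C_DIABETES_PCT
    ):
        raise ValueError("baseline profile meets diabetes thresholds; not at risk")
    if physician_record_flag:
        return True
    if followup_fpg is None and followup_hba1c is None:
        return False
    return ada_diabetes(
        followup_fpg, followup_hba1c, second_sample_abnormal, unequivocal_hyperglycaemia
    )


def homa_ir(fasting_insulin: float, fpg_mmol: float) -> float:
    """HOMA-IR = fasting insulin (uU/mL) x fasting glucose (mmol/L) / 22.5."""
    if fasting_insulin <= 0 or fpg_mmol <= 0:
        raise ValueError("insulin and glucose must be positive")
    return fasting_insulin * fpg_mmol / 22.5


def fpg_mgdl_to_mmol(fpg_mgdl: float) -> float:
    return fpg_mgdl / MGDL_PER_MMOL


def hba1c_ngsp_to_ifcc(hba1c_pct: float) -> float:
    """Convert NGSP % to IFCC mmol/mol via the master equation
    ``(x - 2.15) * 10.929``, reported to one decimal."""
    if not (2.0 <= hba1c_pct < 20.0):
        raise ValueError(f"hba1c {hba1c_pct}% outside plausible range")
    return round((hba1c_pct - _IFCC_OFFSET) * _IFCC_SLOPE, 1)


def hba1c_ifcc_to_ngsp(hba1c_mmol_mol: float) -> float:
    """Inverse of the master equation (unrounded)."""
    return hba1c_mmol_mol / _IFCC_SLOPE + _IFCC_OFFSET


def _get(profile, field: str):
    if isinstance(profile, Mapping):
        if field in profile:
            value = profile[field]
        else:
            return None
    else:
        value = getattr(profile, field, None)
    if value is None or (isinstance(value, float) and value != value):
        return None
    return value


def _require(profile, field: str):
    value = _get(profile, field)
    if value is None:
        raise ValueError(f"missing field required for ATP-III classification: {field}")
    return value


def metabolic_syndrome(profile) -> MetabolicFlags:
    """ATP-III classification with the printed sex-specific cut-offs.

    Components: waist > 102 cm (males) / > 88 cm (females); triglycerides
    >= 150 mg/dL; HDL < 40 (males) / < 50 (females) mg/dL; blood pressure
    SBP >= 130 or DBP >= 85 mmHg or antihypertensive medication; fasting
    glucose >= 110 mg/dL or antidiabetic therapy.  Strict vs inclusive
    comparisons follow the printed symbols exactly.

    ``profile`` may be a mapping, a pandas row, or any object with fields
    sex, waist, triglycerides, hdl, sbp, dbp, antihypertensive_use, fpg
    (antidiabetic_use optional, default False).
    """
    sex = str(_require(profile, "sex")).lower()
    if sex not in {"male", "female"}:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    waist = _require(profile, "waist")
    tg = _require(profile, "triglycerides")
    hdl = _require(profile, "hdl")
    sbp = _require(profile, "sbp")
    dbp = _require(profile, "dbp")
    bp_meds = bool(_require(profile, "antihypertensive_use"))
    fpg = _require(profile, "fpg")
    dm_therapy = bool(_get(profile, "antidiabetic_use") or False)

    waist_cut = 102.0 if sex == "male" else 88.0
    hdl_cut = 40.0 if sex == "male" else 50.0
    return MetabolicFlags(
        abdominal_obesity=waist > waist_cut,
        hypertriglyceridaemia=tg >= 150.0,
        low_hdl=hdl < hdl_cut,
        high_bp=(sbp >= 130.0) or (dbp >= 85.0) or bp_meds,
        hyperglycaemia=(fpg >= 110.0) or dm_therapy,
    )


def annotate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Annotate a cohort table with derived clinical columns.

    Adds ``homa_ir`` (recomputed from insulin and FPG), ``hba1c_ifcc``,
    the five ATP-III component flags, ``n_components`` and
    ``metabolic_syndrome``.  Returns a copy.
    """
    out = cohort.copy()
    out["homa_ir"] = [
        homa_ir(ins, fpg_mgdl_to_mmol(fpg))
        for ins, fpg in zip(out["fasting_insulin"], out["fpg"])
    ]
    out["hba1c_ifcc"] = [hba1c_ngsp_to_ifcc(x) for x in out["hba1c"]]
    flags = [metabolic_syndrome(row) for _, row in out.iterrows()]
    for name in (
        "abdominal_obesity",
        "hypertriglyceridaemia",
        "low_hdl",
        "high_bp",
        "hyperglycaemia",
    ):
        out[name] = [getattr(f, name) for f in flags]
    out["n_components"] = [f.n_components for f in flags]
    out["metabolic_syndrome"] = [f.metabolic_syndrome for f in flags]
    return out
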