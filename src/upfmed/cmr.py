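"""Composite cardiometabolic risk (CMR) score.

Five binary components, one point each, total 0-5; a score of 3 or more
flags high risk:

1. central obesity — waist >= 94 cm (men) / >= 80 cm (women);
2. dyslipidaemia — HDL < 1.0 mmol/L (men) / < 1.3 (women), or non-HDL
   >= 4.0 mmol/L, or lipid-lowering medication;
3. high blood pressure — SBP >= 130 mm Hg, or DBP >= 85, or
   antihypertensive medication;
4. inflammation — hs-CRP in [3, 10) mg/L; values >= 10 score zero
   (acute-phase exclusion) and are flagged;
5. dysglycaemia — HbA1c >= 5.7 %, or glucose-lowering medication.

Missing inputs raise; a component is never silently scored zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError

__all__ = ["ClinicalMeasures", "CmrResult", "compute_cmr", "score_frame", "hba1c_percent_from_mmol"]

COMPONENTS = ("obesity", "dyslipidaemia", "hypertension", "inflammation", "dysglycaemia")

HIGH_RISK_THRESHOLD = 3

_THRESHOLDS = {
    "waist": {"male": 94.0, "female": 80.0},   # >=, cm
    "hdl": {"male": 1.0, "female": 1.3},       # <, mmol/L
    "non_hdl": 4.0,                            # >=, mmol/L
    "sbp": 130.0,                              # >=, mm Hg
    "dbp": 85.0,                               # >=, mm Hg
    "crp_low": 3.0,                            # >=, mg/L
    "crp_high": 10.0,                          # <, mg/L
    "hba1c": 5.7,                              # >=, %
}


def hba1c_percent_from_mmol(mmol_per_mol: float) -> float:
    """IFCC mmol/mol to NGSP/DCCT percent (linear master equation)."""
    return mmol_per_mol / 10.929 + 2.15


@dataclass(frozen=True)
class ClinicalMeasures:
    sex: str
    waist: float       # cm
    hdl: float         # mmol/L
    non_hdl: float     # mmol/L
    sbp: float         # mm Hg
    dbp: float         # mm Hg
    hscrp: float       # mg/L
    hba1c: float       # percent
    on_lipid_meds: bool = False
    on_bp_meds: bool = False
    on_glucose_meds: bool = False

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("waist", "hdl", "non_hdl", "sbp", "dbp", "hscrp", "hba1c"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise MissingDataError(f"required clinical measure {name!r} is missing")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class CmrResult:
    components: dict
    total: int
    high_risk: bool
    acute_inflammation: bool  # hs-CRP >= 10 mg/L, scored 0 but flagged

    def __post_init__(self):
        assert self.total == sum(self.components.values())
        assert self.high_risk == (self.total >= HIGH_RISK_THRESHOLD)


def compute_cmr(m: ClinicalMeasures) -> CmrResult:
    """Score one participant; thresholds inclusive/exclusive as listed above."""
    t = _THRESHOLDS
    comps = {
        "obesity": int(m.waist >= t["waist"][m.sex]),
        "dyslipidaemia": int(
            (m.hdl < t["hdl"][m.sex]) or (m.non_hdl >= t["non_hdl"]) or m.on_lipid_meds
        ),
        "hypertension": int((m.sbp >= t["sbp"]) or (m.dbp >= t["dbp"]) or m.on_bp_meds),
        "inflammation": int(t["crp_low"] <= m.hscrp < t["crp_high"]),
        "dysglycaemia": int((m.hba1c >= t["hba1c"]) or m.on_glucose_meds),
    }
    total = sum(comps.values())
    return CmrResult(
        components=comps,
        total=total,
        high_risk=total >= HIGH_RISK_THRESHOLD,
        acute_inflammation=m.hscrp >= t["crp_high"],
    )


_REQUIRED_COLS = ("sex", "waist", "hdl", "non_hdl", "sbp", "dbp", "hscrp", "hba1c",
                  "on_lipid_meds", "on_bp_meds", "on_glucose_meds")


def score_frame(clinical: pd.DataFrame) -> pd.DataFrame:
    """Vectorised scoring of a clinical table (one row per participant).

    Returns a frame with the five component indicators, ``cmr`` total,
    ``high_risk`` and ``acute_inflammation`` flags, indexed as the input.
    """
    missing = [c for c in _REQUIRED_COLS if c not in clinical.columns]
    if missing:
        raise MissingDataError(f"clinical table lacks columns: {missing}")
    numeric = clinical[["waist", "hdl", "non_hdl", "sbp", "dbp", "hscrp", "hba1c"]]
    if numeric.isna().any().any():
        bad = numeric.columns[numeric.isna().any()].tolist()
        raise MissingDataError(f"missing clinical values in columns: {bad}")
    male = clinical["sex"].to_numpy() == "male"
    t = _THRESHOLDS
    waist_thr = np.where(male, t["waist"]["male"], t["waist"]["female"])
    hdl_thr = np.where(male, t["hdl"]["male"], t["hdl"]["female"])
    out = pd.DataFrame(index=clinical.index)
    out["obesity"] = (clinical["waist"].to_numpy() >= waist_thr).astype(int)
    out["dyslipidaemia"] = (
        (clinical["hdl"].to_numpy() < hdl_thr)
        | (clinical["non_hdl"].to_numpy() >= t["non_hdl"])
        | clinical["on_lipid_meds"].astype(bool).to_numpy()
    ).astype(int)
    out["hypertension"] = (
        (clinical["sbp"].to_numpy() >= t["sbp"])
        | (clinical["dbp"].to_numpy() >= t["dbp"])
        | clinical["on_bp_meds"].astype(bool).to_numpy()
    ).astype(int)
    crp = clinical["hscrp"].to_numpy()
    out["inflammation"] = ((crp >= t["crp_low"]) & (crp < t["crp_high"])).astype(int)
    out["dysglycaemia"] = (
        (clinical["hba1c"].to_numpy() >= t["hba1c"])
        | clinical["on_glucose_meds"].astype(bool).to_numpy()
    ).astype(int)
    out["cmr"] = out[list(COMPONENTS)].sum(axis=1)
    out["high_risk"] = out["cmr"] >= HIGH_RISK_THRESHOLD
    out["acute_inflammation"] = crp >= t["crp_high"]
    return out
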