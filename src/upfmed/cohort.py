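"""Seeded synthetic-cohort generator.

Emulates the statistical structure of a large occupational cohort with
7-day diet diaries: an ultraprocessed (NOVA 4) energy share with mean
58.3 and SD 11.6 %kcal, a DASH diet-quality score linked to the exposure
by a structural slope of -0.197 points per %kcal, a 0-5 CMR score linked
to diet quality at -0.008 per point with a small direct exposure effect
(0.001), and a misreporting split of 38.4/59.7/1.9 % (under/acceptable/
over).

Misreporting is the built-in confounder: the exposure is drawn as a
mixture over misreporting categories (group means 57.2/58.9/61.2), and
under-reporting also shifts the DASH score (+4.818 points), so that the
crude exposure-mediator slope is -0.212 and the crude Pearson
correlation -0.32 while the covariate-adjusted slope stays at the
structural -0.197. The mediator residual SD (6.844) is the closed-form
solution that makes the crude correlation land on -0.32 given these
paths.

Two modes:

* ``table`` — analysis-ready rows (exposure, mediator, 5-component CMR
  outcome, covariates);
* ``diary`` — raw artifacts: a food-code catalogue, 7-day diary entries
  whose recomputed NOVA 4 energy share reproduces the assigned exposure,
  clinical markers whose threshold exceedances reproduce the latent
  component probabilities, and reported energy intakes that reproduce
  the misreporting split through the Goldberg classifier rather than a
  label.

All randomness derives from the config seed through named sub-streams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats as st
from pydantic import BaseModel, Field, field_validator, model_validator

from ._rng import substream
from .association import mediator_model, outcome_model
from .cmr import score_frame
from .diet import GoldbergParams, compute_bmr_array, default_dash_components, goldberg_cutoffs
from .errors import CalibrationError
from .nova import FoodCode

__all__ = [
    "CovariateEffects",
    "StructuralCoefficients",
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_clinical",
    "component_probabilities",
    "calibrate_generator",
    "build_catalogue",
]

MISREPORTING_ORDER = ("under", "acceptable", "over")

TABLE_COLUMNS = (
    "participant_id", "nova4_pct", "dash", "cmr", "high_risk",
    "age", "sex", "bmi", "smoking", "education", "income", "pal", "misreporting",
)


class CovariateEffects(BaseModel):
    """Per-covariate slopes on a linear predictor (all applied centred)."""

    age: float = 0.0                       # per year
    male: float = 0.0
    bmi: float = 0.0                       # per kg/m^2
    smoker: float = 0.0
    education: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    income: tuple[float, float, float, float, float] = (0.0, 0.0, 0.0, 0.0, 0.0)
    pal: tuple[float, float, float] = (0.0, 0.0, 0.0)
    misreporting: tuple[float, float, float] = (0.0, 0.0, 0.0)  # under/acceptable/over

    model_config = {"frozen": True}


#: Mediator-model covariate effects (DASH points). The under-reporting
#: effect is the confounding path solved jointly with the crude slope
#: target; the rest are small, plausible and unanchored.
_DEFAULT_EFFECTS_MEDIATOR = CovariateEffects(
    age=0.03,
    male=-1.0,
    smoker=-0.8,
    education=(0.0, 0.5, 1.0, 1.5),
    income=(0.0, 0.25, 0.5, 0.75, 1.0),
    misreporting=(4.818269, 0.0, 0.0),
)

#: Outcome-model covariate effects (CMR score units); small and unanchored.
_DEFAULT_EFFECTS_OUTCOME = CovariateEffects(
    age=0.015,
    male=0.15,
    bmi=0.03,
    smoker=0.10,
    education=(0.0, -0.03, -0.06, -0.09),
    income=(0.0, -0.02, -0.04, -0.06, -0.08),
    pal=(0.0, -0.05, -0.10),
    misreporting=(-0.05, 0.0, 0.05),
)


class StructuralCoefficients(BaseModel):
    """Structural effect sizes and scale parameters of the generator."""

    a_exposure_to_mediator: float = -0.197   # DASH points per %kcal
    b_mediator_to_outcome: float = -0.008    # CMR units per DASH point
    c_direct: float = 0.001                  # CMR units per %kcal
    exposure_mean: float = 58.3              # %kcal
    exposure_sd: float = Field(default=11.6, gt=0)
    exposure_group_means: tuple[float, float, float] = (57.2, 58.9, 61.2)
    exposure_group_sds: tuple[float, float, float] = (12.2, 11.2, 11.1)
    mediator_mean: float = 38.5              # DASH points (0-80 scale)
    #: solved so the crude exposure-mediator correlation is -0.32 given
    #: the crude slope -0.212 and exposure SD 11.6 (see docs/methods.md)
    mediator_residual_sd: float = Field(default=6.8442, gt=0)
    covariate_effects_mediator: CovariateEffects = _DEFAULT_EFFECTS_MEDIATOR
    covariate_effects_outcome: CovariateEffects = _DEFAULT_EFFECTS_OUTCOME
    component_base_probs: tuple[float, float, float, float, float] = (
        0.35, 0.30, 0.30, 0.10, 0.15,
    )
    prob_clip: tuple[float, float] = (0.02, 0.98)
    #: pilot-calibration scales on the latent outcome slopes (identity by
    #: default: the clipping band almost never binds at default effects)
    outcome_scale_b: float = 1.0
    outcome_scale_c: float = 1.0

    model_config = {"frozen": True}


class CategoryProbabilities(BaseModel):
    income: tuple[float, ...] = (0.15, 0.25, 0.30, 0.20, 0.10)
    education: tuple[float, ...] = (0.10, 0.30, 0.35, 0.25)
    pal: tuple[float, ...] = (0.25, 0.50, 0.25)
    smoking: tuple[float, ...] = (0.85, 0.15)  # non_smoker, current_smoker

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _sum_to_one(self):
        for name in ("income", "education", "pal", "smoking"):
            v = getattr(self, name)
            if abs(sum(v) - 1.0) > 1e-9 or any(p < 0 for p in v):
                raise ValueError(f"{name} probabilities must be >= 0 and sum to 1")
        return self


class CohortConfig(BaseModel):
    n: int = Field(default=9009, ge=0)
    seed: int = 0
    mode: str = "table"
    age_mean: float = 40.9
    age_sd: float = Field(default=9.2, gt=0)
    male_fraction: float = Field(default=0.608, ge=0, le=1)
    bmi_mean: float = 27.3
    bmi_sd: float = Field(default=4.3, gt=0)
    category_probabilities: CategoryProbabilities = CategoryProbabilities()
    misreporting_proportions: tuple[float, float, float] = (0.384, 0.597, 0.019)
    coefficients: StructuralCoefficients = StructuralCoefficients()
    goldberg: GoldbergParams = GoldbergParams()

    model_config = {"frozen": True}

    @field_validator("mode")
    @classmethod
    def _mode_ok(cls, v):
        if v not in ("table", "diary"):
            raise ValueError("mode must be 'table' or 'diary'")
        return v

    @model_validator(mode="after")
    def _misrep_sum(self):
        v = self.misreporting_proportions
        if abs(sum(v) - 1.0) > 1e-9 or any(p < 0 for p in v):
            raise ValueError("misreporting_proportions must be >= 0 and sum to 1")
        return self


@dataclass
class Cohort:
    """Generated tables; diary-mode runs also carry the raw artifacts."""

    table: pd.DataFrame
    config: CohortConfig
    participants: Optional[pd.DataFrame] = None
    clinical: Optional[pd.DataFrame] = None
    diary: Optional[pd.DataFrame] = None
    catalogue: Optional[pd.DataFrame] = None
    catalogue_codes: Optional[dict] = None


# --------------------------------------------------------------------------
# covariates and structural equations
# --------------------------------------------------------------------------

def _centred_effect(levels: np.ndarray, effects, probs) -> np.ndarray:
    eff = np.asarray(effects, float)
    p = np.asarray(probs, float)
    return eff[levels] - float(p @ eff)


def _covariate_contribution(eff: CovariateEffects, cfg: CohortConfig, cov) -> np.ndarray:
    cp = cfg.category_probabilities
    out = (
        eff.age * (cov["age"] - cfg.age_mean)
        + eff.male * (cov["male"].astype(float) - cfg.male_fraction)
        + eff.bmi * (cov["bmi"] - cfg.bmi_mean)
        + eff.smoker * (cov["smoker"].astype(float) - cp.smoking[1])
        + _centred_effect(cov["education_i"], eff.education, cp.education)
        + _centred_effect(cov["income_i"], eff.income, cp.income)
        + _centred_effect(cov["pal_i"], eff.pal, cp.pal)
        + _centred_effect(cov["misrep_i"], eff.misreporting, cfg.misreporting_proportions)
    )
    return out


def _draw_covariates(cfg: CohortConfig) -> dict:
    n = cfg.n
    cp = cfg.category_probabilities
    rng = substream(cfg.seed, "covariates")
    cov = {
        "misrep_i": rng.choice(3, size=n, p=cfg.misreporting_proportions),
        "age": np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), 18.0, 75.0),
        "male": rng.random(n) < cfg.male_fraction,
        "bmi": np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 16.0, 55.0),
        "smoker": rng.random(n) < cp.smoking[1],
        "education_i": rng.choice(4, size=n, p=cp.education),
        "income_i": rng.choice(5, size=n, p=cp.income),
        "pal_i": rng.choice(3, size=n, p=cp.pal),
    }
    return cov


def _draw_exposure(cfg: CohortConfig, misrep_i: np.ndarray) -> np.ndarray:
    """Misreporting-category mixture recentred/rescaled to the configured moments."""
    sc = cfg.coefficients
    p = np.asarray(cfg.misreporting_proportions)
    mu = np.asarray(sc.exposure_group_means, float)
    sd = np.asarray(sc.exposure_group_sds, float)
    mu_adj = mu + (sc.exposure_mean - float(p @ mu))
    between = float(p @ (mu_adj - sc.exposure_mean) ** 2)
    within = float(p @ sd**2)
    if sc.exposure_sd**2 <= between:
        raise ValueError("exposure_sd too small for the configured group means")
    k = np.sqrt((sc.exposure_sd**2 - between) / within)
    rng = substream(cfg.seed, "exposure")
    x = mu_adj[misrep_i] + k * sd[misrep_i] * rng.standard_normal(cfg.n)
    return np.clip(x, 0.0, 100.0)


def _dash_max() -> float:
    return sum(s.max_points for s in default_dash_components())


def _draw_mediator(cfg: CohortConfig, x: np.ndarray, cov) -> np.ndarray:
    sc = cfg.coefficients
    lin = (
        sc.mediator_mean
        + sc.a_exposure_to_mediator * (x - sc.exposure_mean)
        + _covariate_contribution(sc.covariate_effects_mediator, cfg, cov)
    )
    rng = substream(cfg.seed, "mediator")
    m = lin + sc.mediator_residual_sd * rng.standard_normal(cfg.n)
    return np.clip(m, 0.0, _dash_max())


def _latent_outcome(cfg: CohortConfig, x: np.ndarray, m: np.ndarray, cov) -> np.ndarray:
    sc = cfg.coefficients
    return (
        sc.outcome_scale_c * sc.c_direct * (x - sc.exposure_mean)
        + sc.outcome_scale_b * sc.b_mediator_to_outcome * (m - sc.mediator_mean)
        + _covariate_contribution(sc.covariate_effects_outcome, cfg, cov)
    )


def component_probabilities(
    latent_risk: np.ndarray, coefficients: StructuralCoefficients | None = None
) -> np.ndarray:
    """n x 5 component probabilities: base + latent/5, clipped to the band."""
    sc = coefficients or StructuralCoefficients()
    base = np.asarray(sc.component_base_probs, float)
    eta = np.asarray(latent_risk, float)
    p = base[None, :] + eta[:, None] / len(base)
    return np.clip(p, sc.prob_clip[0], sc.prob_clip[1])


# --------------------------------------------------------------------------
# clinical-marker synthesis
# --------------------------------------------------------------------------

_MEDS_PROBS = {"on_lipid_meds": 0.02, "on_bp_meds": 0.03, "on_glucose_meds": 0.01}
_SECONDARY = {"non_hdl": 0.03, "dbp": 0.05}  # fixed exceedance of secondary markers
# log-scale SD of hs-CRP; 0.6 keeps the [3, 10) band attainable up to ~0.68
_CRP_LOG_SD = 0.6


def _mu_for_crp_band(p_target: np.ndarray, s: float = _CRP_LOG_SD) -> np.ndarray:
    """log-mean of CRP so that P(3 <= CRP < 10) = p_target (increasing branch)."""
    lo, hi = np.log(3.0), np.log(10.0)
    peak = 0.5 * (lo + hi)
    p_max = st.norm.cdf((hi - peak) / s) - st.norm.cdf((lo - peak) / s)
    p = np.minimum(np.asarray(p_target, float), p_max - 1e-6)
    a = np.full(p.shape, -8.0)
    b = np.full(p.shape, peak)
    for _ in range(50):
        mid = 0.5 * (a + b)
        val = st.norm.cdf((hi - mid) / s) - st.norm.cdf((lo - mid) / s)
        below = val < p
        a = np.where(below, mid, a)
        b = np.where(below, b, mid)
    return 0.5 * (a + b)


def generate_clinical(
    latent_risk: np.ndarray,
    sex: np.ndarray,
    *,
    coefficients: StructuralCoefficients | None = None,
    rng: np.random.Generator | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical markers whose threshold exceedances follow the latent risk.

    Each CMR component's probability is a clipped linear function of
    ``latent_risk``; markers are drawn from sex-specific Gaussians whose
    means are positioned so the scoring thresholds are exceeded with
    exactly those probabilities (composite components discount the fixed
    secondary-path and medication probabilities).
    """
    rng = rng if rng is not None else substream(seed, "clinical")
    sex = np.asarray(sex, dtype=object)
    male = sex == "male"
    n = len(sex)
    if not np.isfinite(np.asarray(latent_risk, float)).all():
        raise ValueError("latent_risk must be finite")
    p = component_probabilities(latent_risk, coefficients)
    p_obes, p_dys, p_htn, p_infl, p_gly = (p[:, j] for j in range(5))

    def _solve_primary(p_comp, *secondary):
        keep = np.prod([1.0 - s for s in secondary])
        return np.clip(1.0 - (1.0 - p_comp) / keep, 1e-4, 1.0 - 1e-4)

    q = st.norm.ppf
    out = pd.DataFrame({"sex": sex})

    waist_thr = np.where(male, 94.0, 80.0)
    out["waist"] = np.clip(waist_thr + 10.0 * q(p_obes) + 10.0 * rng.standard_normal(n), 50.0, None)

    p_hdl = _solve_primary(p_dys, _MEDS_PROBS["on_lipid_meds"], _SECONDARY["non_hdl"])
    hdl_thr = np.where(male, 1.0, 1.3)
    out["hdl"] = np.clip(hdl_thr - 0.35 * q(p_hdl) + 0.35 * rng.standard_normal(n), 0.3, None)
    mu_nonhdl = 4.0 - 0.9 * q(1.0 - _SECONDARY["non_hdl"])
    out["non_hdl"] = np.clip(mu_nonhdl + 0.9 * rng.standard_normal(n), 0.5, None)

    p_sbp = _solve_primary(p_htn, _MEDS_PROBS["on_bp_meds"], _SECONDARY["dbp"])
    out["sbp"] = np.clip(130.0 + 15.0 * q(p_sbp) + 15.0 * rng.standard_normal(n), 80.0, None)
    mu_dbp = 85.0 - 10.0 * q(1.0 - _SECONDARY["dbp"])
    out["dbp"] = np.clip(mu_dbp + 10.0 * rng.standard_normal(n), 40.0, None)

    out["hscrp"] = np.exp(_mu_for_crp_band(p_infl) + _CRP_LOG_SD * rng.standard_normal(n))

    p_hba1c = _solve_primary(p_gly, _MEDS_PROBS["on_glucose_meds"])
    out["hba1c"] = np.clip(5.7 + 0.45 * q(p_hba1c) + 0.45 * rng.standard_normal(n), 3.5, None)

    for name, prob in _MEDS_PROBS.items():
        out[name] = rng.random(n) < prob
    return out


# --------------------------------------------------------------------------
# food catalogue and diaries
# --------------------------------------------------------------------------

def _macros(fat=0.0, satfat=0.0, carbohydrate=0.0, protein=0.0, nmes=0.0, fibre=0.0):
    nut = dict(fat=fat, satfat=satfat, carbohydrate=carbohydrate, protein=protein,
               nmes=nmes, fibre=fibre)
    energy = 9.0 * fat + 4.0 * protein + 3.75 * carbohydrate
    return energy, nut


#: DASH component -> (anchor code id, latent NOVA group of the anchor)
_ANCHORS = {
    "fruit": "fruit_apple",
    "vegetables": "veg_carrot",
    "wholegrains": "grain_oats",
    "nuts_legumes": "legume_lentils",
    "low_fat_dairy": "dairy_milk",
    "red_processed_meat": "meat_sausage",
    "sweetened_drinks": "drink_cola",
    "sodium": "cond_salt",
}
_FILLER_UPF = "meal_tikka"
_FILLER_MIN = "staple_rice"
_BEVERAGE = "drink_tea"


def build_catalogue() -> tuple[dict[str, FoodCode], pd.DataFrame]:
    """Small synthetic food-code catalogue standing in for a national
    food-composition database; descriptors are designed so the rule-based
    NOVA classification reproduces each code's latent group."""
    def fc(code_id, description, latent, origin="unspecified", brand=None,
           ingredients=(), food_groups=None, beverage=False, **macros):
        energy, nut = _macros(**macros)
        return (
            FoodCode(
                code_id=code_id, description=description, origin=origin,
                brand_name=brand, ingredient_code_ids=tuple(ingredients),
                energy_per_100g=energy, nutrients_per_100g=nut,
                food_groups=food_groups or {}, is_beverage=beverage,
            ),
            latent,
        )

    rows = [
        fc("fruit_apple", "apple raw", 1, food_groups={"fruit": 100.0},
           carbohydrate=11.8, nmes=0.0, fibre=1.8),
        fc("veg_carrot", "carrots boiled", 1, food_groups={"vegetables": 100.0},
           carbohydrate=4.9, protein=0.6, fibre=2.8),
        fc("grain_oats", "porridge oats", 1, food_groups={"wholegrains": 100.0},
           carbohydrate=60.0, protein=11.0, fat=8.0, satfat=1.5, fibre=9.0),
        fc("legume_lentils", "lentils boiled", 1, food_groups={"nuts_legumes": 100.0},
           carbohydrate=17.0, protein=7.6, fat=0.4, fibre=1.9),
        fc("dairy_milk", "milk semi-skimmed", 1, food_groups={"low_fat_dairy": 100.0},
           beverage=True, carbohydrate=4.8, protein=3.4, fat=1.7, satfat=1.1),
        fc("cond_salt", "table salt", 2, food_groups={"sodium": 38758.0}),
        fc("meat_sausage", "pork sausages grilled", 4, origin="retail",
           food_groups={"red_processed_meat": 100.0},
           fat=22.0, satfat=8.0, protein=13.0, carbohydrate=9.0),
        fc("drink_cola", "cola soft drink", 4, brand="FizzCo", beverage=True,
           food_groups={"sweetened_drinks": 100.0}, carbohydrate=10.6, nmes=10.6),
        fc("meal_tikka", "chicken tikka masala with pilau", 4, origin="retail",
           brand="QuickFoods", fat=8.0, satfat=3.0, protein=8.0, carbohydrate=12.0,
           nmes=1.5, fibre=1.0),
        fc("staple_rice", "rice white boiled", 1,
           carbohydrate=28.0, protein=2.6, fat=0.3, fibre=0.5),
        fc("drink_tea", "tea infusion", 1, beverage=True),
        # rule-exercising extras (rarely eaten, present for classification)
        fc("sauce_cookin", "pasta sauce cook-in", 4, origin="retail",
           carbohydrate=8.0, fat=3.0, protein=1.5, nmes=4.0),
        fc("beef_mince_hm", "beef minced stewed", 3, origin="homemade",
           fat=14.0, satfat=6.0, protein=22.0),
        fc("lasagne_hm", "lasagne", 4, origin="homemade",
           ingredients=("sauce_cookin", "beef_mince_hm"),
           fat=9.0, satfat=4.0, protein=9.0, carbohydrate=12.0, fibre=1.0),
        fc("tuna_tin", "tuna tinned in brine", 4,
           protein=24.0, fat=0.6),
        fc("mystery_dish", "mixed savoury dish", 4),
    ]
    catalogue = {c.code_id: c for c, _ in rows}
    frame = pd.DataFrame(
        {
            "code_id": [c.code_id for c, _ in rows],
            "description": [c.description for c, _ in rows],
            "origin": [c.origin for c, _ in rows],
            "brand_name": [c.brand_name or "" for c, _ in rows],
            "ingredient_code_ids": ["|".join(c.ingredient_code_ids) for c, _ in rows],
            "energy_per_100g": [c.energy_per_100g for c, _ in rows],
            "is_beverage": [c.is_beverage for c, _ in rows],
            "latent_nova": [g for _, g in rows],
            **{
                f"{nut}_per_100g": [c.nutrients_per_100g.get(nut, 0.0) for c, _ in rows]
                for nut in ("fat", "satfat", "carbohydrate", "protein", "nmes", "fibre")
            },
        }
    )
    return catalogue, frame


def _component_scores(cfg: CohortConfig, m: np.ndarray) -> np.ndarray:
    """n x 8 component scores summing approximately to the assigned DASH."""
    specs = default_dash_components()
    k = len(specs)
    lo = np.array([0.0 if s.direction == "adequacy" else 1.5 for s in specs])
    hi = np.array([s.max_points for s in specs])
    rng = substream(cfg.seed, "dash-split")
    s = m[:, None] / k + rng.normal(0.0, 0.8, size=(cfg.n, k))
    s = np.clip(s, lo, hi)
    for _ in range(15):
        deficit = m - s.sum(axis=1)
        s = np.clip(s + deficit[:, None] / k, lo, hi)
    return s


def _intakes_from_scores(cfg: CohortConfig, scores: np.ndarray) -> np.ndarray:
    """Invert the DASH scoring rule: daily component intakes per participant."""
    specs = default_dash_components()
    rng = substream(cfg.seed, "dash-intakes")
    n, k = scores.shape
    u = rng.random((n, k))
    out = np.empty_like(scores)
    for j, spec in enumerate(specs):
        s = scores[:, j]
        full = s >= spec.max_points - 1e-9
        if spec.direction == "adequacy":
            out[:, j] = np.where(
                full,
                spec.daily_target * (1.0 + 0.5 * u[:, j]),
                spec.daily_target * s / spec.max_points,
            )
        else:
            with np.errstate(divide="ignore"):
                above = spec.daily_target * spec.max_points / np.maximum(s, 1e-9)
            out[:, j] = np.where(
                full, spec.daily_target * (0.4 + 0.6 * u[:, j]), above
            )
    return out


def _build_diary(
    cfg: CohortConfig,
    pid: np.ndarray,
    x: np.ndarray,
    m: np.ndarray,
    daily_energy: np.ndarray,
    catalogue: dict[str, FoodCode],
    latent: dict[str, int],
) -> pd.DataFrame:
    """7-day diaries hitting the assigned NOVA 4 energy share exactly.

    DASH anchor foods carry the food-group intakes implied by the
    assigned score; two filler staples absorb the remaining energy in
    each NOVA stratum. When an energy budget cannot absorb its anchors,
    anchor grams are rescaled (preserving the share at some cost in DASH
    fidelity).
    """
    n = cfg.n
    specs = default_dash_components()
    scores = _component_scores(cfg, m)
    intakes = _intakes_from_scores(cfg, scores)

    anchor_ids = [_ANCHORS[s.name] for s in specs]
    grams = np.empty((n, len(anchor_ids)))
    for j, (spec, cid) in enumerate(zip(specs, anchor_ids)):
        per100 = catalogue[cid].food_groups[spec.name]
        grams[:, j] = intakes[:, j] * 100.0 / per100
    e100 = np.array([catalogue[c].energy_per_100g for c in anchor_ids])
    is4 = np.array([latent[c] == 4 for c in anchor_ids])
    e_anchor = grams * e100[None, :] / 100.0
    e4_anchor = e_anchor[:, is4].sum(axis=1)
    eo_anchor = e_anchor[:, ~is4].sum(axis=1)

    f = x / 100.0
    e4_target = f * daily_energy
    eo_target = (1.0 - f) * daily_energy
    with np.errstate(divide="ignore", invalid="ignore"):
        scale4 = np.where(e4_anchor > e4_target, e4_target / np.maximum(e4_anchor, 1e-12), 1.0)
        scaleo = np.where(eo_anchor > eo_target, eo_target / np.maximum(eo_anchor, 1e-12), 1.0)
    grams[:, is4] *= scale4[:, None]
    grams[:, ~is4] *= scaleo[:, None]
    fill4 = np.maximum(e4_target - e4_anchor * scale4, 0.0)
    fillo = np.maximum(eo_target - eo_anchor * scaleo, 0.0)

    code_ids = anchor_ids + [_FILLER_UPF, _FILLER_MIN, _BEVERAGE]
    all_grams = np.column_stack(
        [
            grams,
            fill4 * 100.0 / catalogue[_FILLER_UPF].energy_per_100g,
            fillo * 100.0 / catalogue[_FILLER_MIN].energy_per_100g,
            np.full(n, 250.0),  # zero-energy beverage, exercises exclusions
        ]
    )

    rng = substream(cfg.seed, "diary-days")
    w = np.clip(1.0 + 0.25 * rng.standard_normal((n, 7)), 0.3, None)
    w *= 7.0 / w.sum(axis=1, keepdims=True)

    k = len(code_ids)
    pid_col = np.repeat(pid, k * 7)
    day_col = np.tile(np.repeat(np.arange(1, 8), k), n)
    code_col = np.tile(code_ids, 7 * n)
    gram_col = (all_grams[:, None, :] * w[:, :, None]).reshape(-1)
    diary = pd.DataFrame(
        {"participant_id": pid_col, "day": day_col, "code_id": code_col,
         "grams": gram_col}
    )
    return diary[diary["grams"] > 1e-9].reset_index(drop=True)


def _draw_ei_ratio(cfg: CohortConfig, misrep_i: np.ndarray) -> np.ndarray:
    """Reported EI:BMR ratios drawn inside each Goldberg category's interval,
    so the classifier (not a label) reproduces the misreporting split."""
    lo, hi = goldberg_cutoffs(cfg.goldberg)
    pal = cfg.goldberg.pal
    bounds = np.log(
        np.array([[0.70, lo * 0.999], [lo * 1.001, hi * 0.999], [hi * 1.001, 2.90]])
    )
    mu, sigma = np.log(pal), 0.25
    a = (bounds[misrep_i, 0] - mu) / sigma
    b = (bounds[misrep_i, 1] - mu) / sigma
    rng = substream(cfg.seed, "energy-intake")
    u = rng.random(cfg.n)
    return np.exp(st.truncnorm.ppf(u, a, b, loc=mu, scale=sigma))


# --------------------------------------------------------------------------
# top-level generation
# --------------------------------------------------------------------------

def _labels(cov, cfg) -> dict:
    from .association import CATEGORY_LEVELS

    edu = np.array(CATEGORY_LEVELS["education"], dtype=object)
    inc = np.array(CATEGORY_LEVELS["income"], dtype=object)
    pal = np.array(CATEGORY_LEVELS["pal"], dtype=object)
    mis = np.array(MISREPORTING_ORDER, dtype=object)
    return {
        "sex": np.where(cov["male"], "male", "female"),
        "smoking": np.where(cov["smoker"], "current_smoker", "non_smoker"),
        "education": edu[cov["education_i"]],
        "income": inc[cov["income_i"]],
        "pal": pal[cov["pal_i"]],
        "misreporting": mis[cov["misrep_i"]],
    }


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate one cohort; deterministic given the config (incl. seed)."""
    cfg = config
    n = cfg.n
    cov = _draw_covariates(cfg)
    x = _draw_exposure(cfg, cov["misrep_i"])
    m = _draw_mediator(cfg, x, cov)
    eta = _latent_outcome(cfg, x, m, cov)
    labels = _labels(cov, cfg)
    pid = np.array([f"P{i:07d}" for i in range(n)], dtype=object)

    clinical = generate_clinical(
        eta, labels["sex"], coefficients=cfg.coefficients,
        rng=substream(cfg.seed, "clinical"),
    )
    clinical.insert(0, "participant_id", pid)
    scored = score_frame(clinical)

    table = pd.DataFrame(
        {
            "participant_id": pid,
            "nova4_pct": x,
            "dash": m,
            "cmr": scored["cmr"].to_numpy(),
            "high_risk": scored["high_risk"].to_numpy(),
            "age": cov["age"],
            "sex": labels["sex"],
            "bmi": cov["bmi"],
            "smoking": labels["smoking"],
            "education": labels["education"],
            "income": labels["income"],
            "pal": labels["pal"],
            "misreporting": labels["misreporting"],
        },
        columns=list(TABLE_COLUMNS),
    )

    if cfg.mode == "table":
        return Cohort(table=table, config=cfg)

    # diary mode: raw artifacts from which every table column can be re-derived
    rng_h = substream(cfg.seed, "height")
    height = np.where(
        cov["male"],
        rng_h.normal(1.76, 0.07, n),
        rng_h.normal(1.62, 0.065, n),
    )
    height = np.clip(height, 1.40, 2.10)
    weight = cov["bmi"] * height**2
    bmr = compute_bmr_array(cov["age"], cov["male"], weight)
    ratio = _draw_ei_ratio(cfg, cov["misrep_i"])
    mean_ei = ratio * bmr

    participants = pd.DataFrame(
        {
            "participant_id": pid,
            "age": cov["age"],
            "sex": labels["sex"],
            "bmi": cov["bmi"],
            "height_m": height,
            "weight_kg": weight,
            "smoking": labels["smoking"],
            "education": labels["education"],
            "income": labels["income"],
            "pal": labels["pal"],
        }
    )
    catalogue, cat_frame = build_catalogue()
    latent = dict(zip(cat_frame["code_id"], cat_frame["latent_nova"]))
    diary = _build_diary(cfg, pid, x, m, mean_ei, catalogue, latent)
    return Cohort(
        table=table,
        config=cfg,
        participants=participants,
        clinical=clinical,
        diary=diary,
        catalogue=cat_frame,
        catalogue_codes=catalogue,
    )


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def calibrate_generator(
    targets: StructuralCoefficients | None = None,
    n_pilot: int = 20000,
    seed: int = 0,
    tol_se: float = 2.0,
    max_iter: int = 8,
) -> dict:
    """Pilot-fit the outcome slopes and adjust the latent scales.

    Generates pilot cohorts, fits the adjusted mediator and outcome
    models, and multiplies the latent outcome scales by target/fitted
    until both fitted slopes are within ``tol_se`` standard errors of
    their targets. Returns the scales plus diagnostics; deterministic
    given the seed. Raises :class:`CalibrationError` on non-convergence.
    """
    if n_pilot < 10000:
        raise ValueError("n_pilot must be >= 10000")
    coeffs = targets or StructuralCoefficients()
    s_b, s_c = coeffs.outcome_scale_b, coeffs.outcome_scale_c
    history = []
    for it in range(max_iter):
        trial = coeffs.model_copy(update={"outcome_scale_b": s_b, "outcome_scale_c": s_c})
        cfg = CohortConfig(n=n_pilot, seed=seed, coefficients=trial)
        table = generate_cohort(cfg).table
        med = mediator_model(table, variant="text")
        out = outcome_model(table, adjust_for_diet_quality=True)
        a_hat = med.params["nova4_pct"]
        b_hat, b_se = out.params["dash"], out.bse["dash"]
        c_hat, c_se = out.params["nova4_pct"], out.bse["nova4_pct"]
        history.append(
            {"iter": it, "a_hat": float(a_hat), "b_hat": float(b_hat),
             "c_hat": float(c_hat), "scale_b": s_b, "scale_c": s_c}
        )
        ok_b = abs(b_hat - coeffs.b_mediator_to_outcome) < tol_se * b_se
        ok_c = abs(c_hat - coeffs.c_direct) < tol_se * c_se
        if ok_b and ok_c:
            return {
                "outcome_scale_b": float(s_b),
                "outcome_scale_c": float(s_c),
                "converged": True,
                "iterations": it + 1,
                "history": history,
            }
        if coeffs.b_mediator_to_outcome != 0 and abs(b_hat) > 1e-12:
            s_b *= coeffs.b_mediator_to_outcome / b_hat
        if coeffs.c_direct != 0 and abs(c_hat) > 1e-12:
            s_c *= coeffs.c_direct / c_hat
    raise CalibrationError(
        f"calibration did not converge in {max_iter} iterations",
        diagnostics={"history": history},
    )
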