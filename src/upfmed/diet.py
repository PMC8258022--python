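"""Diet-quality measures from 7-day food diaries.

Three per-participant summaries:

* a nutrient profile (mean daily energy, % energy from fat, saturated
  fat, carbohydrate, protein and non-milk extrinsic sugars, fibre
  density per 1000 kcal, dietary energy density over solid foods);
* a DASH adherence score: a food-group point index where adequacy
  components award points proportional to intake up to a daily target
  and moderation components decay above it;
* Goldberg misreporting status from the ratio of reported energy intake
  to Schofield-predicted basal metabolic rate.

Energy conversion uses the UK food-table factors (fat 9, protein 4,
carbohydrate and NMES 3.75 kcal/g), so percentages close to ~100% on a
diary whose energy comes entirely from the three macronutrients.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .errors import MissingDataError
from .nova import FoodCode

__all__ = [
    "ENERGY_FACTORS",
    "NutrientProfile",
    "DashComponentSpec",
    "DashScore",
    "GoldbergParams",
    "MISREPORTING_LEVELS",
    "compute_nutrient_profile",
    "food_group_intakes",
    "default_dash_components",
    "compute_dash_score",
    "compute_bmr",
    "goldberg_cutoffs",
    "goldberg_classify",
]

#: kcal per gram, UK food-table convention (carbohydrate as monosaccharide
#: equivalent at 3.75, not the Atwater 4).
ENERGY_FACTORS = {"fat": 9.0, "protein": 4.0, "carbohydrate": 3.75, "nmes": 3.75}

MISREPORTING_LEVELS = ("under", "acceptable", "over")


@dataclass(frozen=True)
class NutrientProfile:
    mean_daily_energy: float            # kcal/day
    pct_energy_fat: float
    pct_energy_satfat: float
    pct_energy_carbohydrate: float
    pct_energy_protein: float
    pct_energy_nmes: float
    fibre_density: float                # g per 1000 kcal
    energy_density: float               # kcal per g, solid foods only


def compute_nutrient_profile(
    entries: Iterable, catalogue: Mapping[str, FoodCode]
) -> NutrientProfile:
    """Nutrient profile over a diary (any number of days >= 1).

    Energy density is computed over solid foods only; beverages are
    excluded from both its numerator and denominator.
    """
    totals = {k: 0.0 for k in ("energy", "fat", "satfat", "carbohydrate", "protein", "nmes", "fibre")}
    solid_energy = solid_grams = 0.0
    days = set()
    for entry in entries:
        if isinstance(entry, Mapping):
            cid, grams, day = entry["code_id"], entry["grams"], entry.get("day", 1)
        else:
            cid, grams, day = entry.code_id, entry.grams, entry.day
        code = catalogue[cid]
        days.add(day)
        factor = grams / 100.0
        totals["energy"] += factor * code.energy_per_100g
        for nut in ("fat", "satfat", "carbohydrate", "protein", "nmes", "fibre"):
            totals[nut] += factor * code.nutrients_per_100g.get(nut, 0.0)
        if not code.is_beverage:
            solid_energy += factor * code.energy_per_100g
            solid_grams += grams
    if not days or totals["energy"] <= 0:
        raise MissingDataError("diary has no entries with positive energy")
    energy = totals["energy"]
    pct = {
        nut: 100.0 * totals[nut] * ENERGY_FACTORS[f] / energy
        for nut, f in (
            ("fat", "fat"),
            ("satfat", "fat"),
            ("carbohydrate", "carbohydrate"),
            ("protein", "protein"),
            ("nmes", "nmes"),
        )
    }
    return NutrientProfile(
        mean_daily_energy=energy / len(days),
        pct_energy_fat=pct["fat"],
        pct_energy_satfat=pct["satfat"],
        pct_energy_carbohydrate=pct["carbohydrate"],
        pct_energy_protein=pct["protein"],
        pct_energy_nmes=pct["nmes"],
        fibre_density=1000.0 * totals["fibre"] / energy,
        energy_density=(solid_energy / solid_grams) if solid_grams > 0 else 0.0,
    )


# --------------------------------------------------------------------------
# DASH adherence score
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DashComponentSpec:
    name: str
    daily_target: float
    direction: str  # "adequacy" | "moderation"
    max_points: float = 10.0

    def __post_init__(self):
        if self.daily_target <= 0:
            raise ValueError(f"{self.name}: daily_target must be > 0")
        if self.max_points <= 0:
            raise ValueError(f"{self.name}: max_points must be > 0")
        if self.direction not in ("adequacy", "moderation"):
            raise ValueError(f"{self.name}: unknown direction {self.direction!r}")


@dataclass(frozen=True)
class DashScore:
    total: float
    per_component: Mapping[str, float]
    normalised: float  # total rescaled to 0-10

    def __post_init__(self):
        assert abs(self.total - sum(self.per_component.values())) < 1e-9


def default_dash_components() -> tuple[DashComponentSpec, ...]:
    raw = yaml.safe_load(
        resources.files("upfmed.data").joinpath("dash_components.yaml").read_text()
    )
    return tuple(DashComponentSpec(**c) for c in raw["components"])


def load_dash_components(path) -> tuple[DashComponentSpec, ...]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(DashComponentSpec(**c) for c in raw["components"])


def compute_dash_score(
    food_group_intakes: Mapping[str, float],
    specs: Sequence[DashComponentSpec] | None = None,
) -> DashScore:
    """Point score per component; total is the raw sum over components.

    Adequacy: ``max_points * min(1, intake/target)`` — proportional up to
    the daily target. Moderation: full points at or below the target,
    ``max_points * target/intake`` above it.
    """
    specs = specs if specs is not None else default_dash_components()
    if not specs:
        raise ValueError("specs must be non-empty")
    per: dict[str, float] = {}
    for spec in specs:
        intake = float(food_group_intakes.get(spec.name, 0.0))
        if intake < 0:
            raise ValueError(f"negative intake for component {spec.name!r}")
        if spec.direction == "adequacy":
            pts = spec.max_points * min(1.0, intake / spec.daily_target)
        else:
            pts = spec.max_points if intake <= spec.daily_target else spec.max_points * spec.daily_target / intake
        per[spec.name] = pts
    total = sum(per.values())
    max_total = sum(s.max_points for s in specs)
    return DashScore(total=total, per_component=per, normalised=10.0 * total / max_total)


def food_group_intakes(
    entries: Iterable, catalogue: Mapping[str, FoodCode], n_days: int | None = None
) -> dict[str, float]:
    """Mean daily food-group amounts from a diary (units per component spec)."""
    totals: dict[str, float] = {}
    days = set()
    for entry in entries:
        if isinstance(entry, Mapping):
            cid, grams, day = entry["code_id"], entry["grams"], entry.get("day", 1)
        else:
            cid, grams, day = entry.code_id, entry.grams, entry.day
        days.add(day)
        for group, amount in catalogue[cid].food_groups.items():
            totals[group] = totals.get(group, 0.0) + grams * amount / 100.0
    d = n_days if n_days is not None else max(len(days), 1)
    return {g: v / d for g, v in totals.items()}


# --------------------------------------------------------------------------
# Basal metabolic rate and Goldberg misreporting cut-offs
# --------------------------------------------------------------------------

# Schofield weight-based equations, kcal/day, adult age bands.
_SCHOFIELD = {
    "male": ((18, 30, 15.057, 692.2), (30, 60, 11.472, 873.1), (60, math.inf, 11.711, 587.7)),
    "female": ((18, 30, 14.818, 486.6), (30, 60, 8.126, 845.6), (60, math.inf, 9.082, 658.5)),
}


def compute_bmr(age: float, sex: str, weight: float) -> float:
    """Schofield basal metabolic rate (kcal/day) for adults."""
    if weight is None or (isinstance(weight, float) and math.isnan(weight)):
        raise MissingDataError("weight is required for BMR")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    if age < 18:
        raise ValueError("adult Schofield bands require age >= 18")
    if sex not in _SCHOFIELD:
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    for lo, hi, slope, intercept in _SCHOFIELD[sex]:
        if lo <= age < hi:
            return slope * weight + intercept
    raise AssertionError("unreachable")


def compute_bmr_array(age: np.ndarray, male: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Vectorised Schofield BMR; ``male`` is a boolean array."""
    age = np.asarray(age, float)
    weight = np.asarray(weight, float)
    out = np.empty_like(weight)
    for sex, bands in _SCHOFIELD.items():
        sel_sex = male if sex == "male" else ~male
        for lo, hi, slope, intercept in bands:
            sel = sel_sex & (age >= lo) & (age < hi)
            out[sel] = slope * weight[sel] + intercept
    return out


class GoldbergParams(BaseModel):
    """Constants of the Goldberg/Black EI:BMR plausibility interval.

    ``cv_within_ei`` is the within-subject CV of energy intake (%),
    attenuated by the number of diary days; ``cv_bmr`` and ``cv_pal``
    the CVs of BMR prediction and physical activity level.
    """

    pal: float = Field(default=1.55, gt=0)
    cv_within_ei: float = Field(default=23.0, gt=0)
    diary_days: int = Field(default=7, gt=0)
    cv_bmr: float = Field(default=8.5, gt=0)
    cv_pal: float = Field(default=15.1, gt=0)
    z: float = Field(default=1.96, gt=0)

    model_config = {"frozen": True}


def goldberg_cutoffs(params: GoldbergParams | None = None) -> tuple[float, float]:
    """(lower, upper) plausible EI:BMR bounds; brackets ``pal`` for any inputs."""
    p = params or GoldbergParams()
    s = math.sqrt(p.cv_within_ei**2 / p.diary_days + p.cv_bmr**2 + p.cv_pal**2)
    return (p.pal * math.exp(-p.z * s / 100.0), p.pal * math.exp(p.z * s / 100.0))


def goldberg_classify(
    mean_ei: float, bmr: float, params: GoldbergParams | None = None
) -> str:
    """Misreporting status from mean daily energy intake and BMR."""
    if bmr <= 0:
        raise ValueError("bmr must be > 0")
    if mean_ei <= 0:
        raise ValueError("mean_ei must be > 0")
    lo, hi = goldberg_cutoffs(params)
    ratio = mean_ei / bmr
    if ratio < lo:
        return "under"
    if ratio > hi:
        return "over"
    return "acceptable"


def goldberg_classify_array(
    mean_ei: np.ndarray, bmr: np.ndarray, params: GoldbergParams | None = None
) -> np.ndarray:
    lo, hi = goldberg_cutoffs(params)
    ratio = np.asarray(mean_ei, float) / np.asarray(bmr, float)
    out = np.full(ratio.shape, "acceptable", dtype=object)
    out[ratio < lo] = "under"
    out[ratio > hi] = "over"
    return out
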