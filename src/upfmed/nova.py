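"""NOVA food-processing classification.

Assigns each food code in a catalogue one of the four NOVA groups
(1 unprocessed/minimally processed, 2 processed culinary ingredient,
3 processed, 4 ultraprocessed) from its descriptor metadata, and computes
the percentage of dietary energy obtained from ultraprocessed (NOVA 4)
items in a food diary.

Ingredient information is usually absent from UK food-composition coding,
so classification leans on descriptor conventions: codes described as
homemade default to NOVA 3, retail codes to NOVA 4, and codes of
unspecified origin are treated as retail when a processing term
("canned", "tinned", ...) or a brand name marks them as manufactured.
A homemade recipe containing at least one NOVA 4 ingredient is promoted
to NOVA 4. Rule precedence is fixed and recorded per code in a rule
trace.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .errors import ClassificationError, UndefinedShareError

__all__ = [
    "FoodCode",
    "DiaryEntry",
    "NovaAssignment",
    "NovaRuleSet",
    "classify_code",
    "classify_catalogue",
    "nova4_energy_share",
    "nova4_share_by_participant",
]

_ORIGINS = ("homemade", "retail", "unspecified")


@dataclass(frozen=True)
class FoodCode:
    """One entry of the food-composition catalogue.

    ``food_groups`` maps DASH component names to the component amount
    contributed per 100 g of this food (grams for food groups, mg for
    sodium). ``nutrients_per_100g`` holds grams of fat, saturated fat,
    carbohydrate, protein, NMES and fibre per 100 g.
    """

    code_id: str
    description: str
    origin: str = "unspecified"
    brand_name: str | None = None
    ingredient_code_ids: tuple[str, ...] = ()
    energy_per_100g: float = 0.0
    nutrients_per_100g: Mapping[str, float] = field(default_factory=dict)
    food_groups: Mapping[str, float] = field(default_factory=dict)
    is_beverage: bool = False

    def __post_init__(self):
        if self.origin not in _ORIGINS:
            raise ValueError(f"origin must be one of {_ORIGINS}, got {self.origin!r}")
        if self.energy_per_100g < 0:
            raise ValueError(f"{self.code_id}: energy_per_100g must be >= 0")


@dataclass(frozen=True)
class DiaryEntry:
    """One eaten item: a participant, a diary day, a food code and grams."""

    participant_id: str
    day: int
    code_id: str
    grams: float

    def __post_init__(self):
        if self.grams < 0:
            raise ValueError("grams must be >= 0")


@dataclass(frozen=True)
class NovaAssignment:
    code_id: str
    nova_group: int
    rule_trace: tuple[str, ...]

    def __post_init__(self):
        if self.nova_group not in (1, 2, 3, 4):
            raise ValueError("nova_group must be in {1,2,3,4}")
        if not self.rule_trace:
            raise ValueError("rule_trace must be non-empty")


@dataclass(frozen=True)
class NovaRuleSet:
    """Keyword tables and precedence parameters for descriptor classification."""

    nova1_keywords: tuple[str, ...]
    nova2_keywords: tuple[str, ...]
    processing_terms: tuple[str, ...]
    default_group: int = 4
    max_ingredient_depth: int = 3

    @classmethod
    def from_yaml(cls, path) -> "NovaRuleSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls._from_dict(raw)

    @classmethod
    def default(cls) -> "NovaRuleSet":
        raw = yaml.safe_load(
            resources.files("upfmed.data").joinpath("nova_rules.yaml").read_text()
        )
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: Mapping) -> "NovaRuleSet":
        return cls(
            nova1_keywords=tuple(k.lower() for k in raw.get("nova1_keywords", [])),
            nova2_keywords=tuple(k.lower() for k in raw.get("nova2_keywords", [])),
            processing_terms=tuple(k.lower() for k in raw.get("processing_terms", [])),
            default_group=int(raw.get("default_group", 4)),
            max_ingredient_depth=int(raw.get("max_ingredient_depth", 3)),
        )


def _match(keywords: Sequence[str], text: str) -> str | None:
    low = text.lower()
    for kw in keywords:
        if kw in low:
            return kw
    return None


def classify_code(
    code: FoodCode,
    catalogue: Mapping[str, FoodCode],
    ruleset: NovaRuleSet | None = None,
    *,
    _memo: dict | None = None,
    _stack: frozenset = frozenset(),
    _depth: int = 0,
) -> NovaAssignment:
    """Classify one food code; pure in (code, catalogue, ruleset).

    Precedence: staple keyword (NOVA 1, then NOVA 2) > homemade with a
    NOVA 4 ingredient > homemade (NOVA 3) > retail (NOVA 4) > unspecified
    with processing term or brand name (treated as retail, NOVA 4) >
    configurable fallback (ships as NOVA 4, the conservative choice when
    a descriptor is uninformative).
    """
    ruleset = ruleset or NovaRuleSet.default()
    memo = _memo if _memo is not None else {}
    if code.code_id in memo:
        return memo[code.code_id]
    if code.code_id in _stack:
        raise ClassificationError(f"ingredient cycle involving code {code.code_id!r}")

    kw = _match(ruleset.nova1_keywords, code.description)
    if kw is not None:
        result = NovaAssignment(code.code_id, 1, (f"staple_nova1:{kw}",))
    else:
        kw = _match(ruleset.nova2_keywords, code.description)
        if kw is not None:
            result = NovaAssignment(code.code_id, 2, (f"staple_nova2:{kw}",))
        elif code.origin == "homemade":
            result = _classify_homemade(code, catalogue, ruleset, memo, _stack, _depth)
        elif code.origin == "retail":
            result = NovaAssignment(code.code_id, 4, ("retail_nova4",))
        else:
            term = _match(ruleset.processing_terms, code.description)
            if term is not None:
                result = NovaAssignment(code.code_id, 4, (f"processing_term:{term}",))
            elif code.brand_name:
                result = NovaAssignment(code.code_id, 4, ("brand_name",))
            else:
                result = NovaAssignment(
                    code.code_id, ruleset.default_group, ("fallback_default",)
                )
    memo[code.code_id] = result
    return result


def _classify_homemade(code, catalogue, ruleset, memo, stack, depth) -> NovaAssignment:
    if code.ingredient_code_ids and depth < ruleset.max_ingredient_depth:
        for ing_id in code.ingredient_code_ids:
            if ing_id not in catalogue:
                raise ClassificationError(
                    f"code {code.code_id!r} references unknown ingredient {ing_id!r}"
                )
            ing = classify_code(
                catalogue[ing_id],
                catalogue,
                ruleset,
                _memo=memo,
                _stack=stack | {code.code_id},
                _depth=depth + 1,
            )
            if ing.nova_group == 4:
                return NovaAssignment(
                    code.code_id, 4, (f"homemade_nova4_ingredient:{ing_id}",)
                )
    return NovaAssignment(code.code_id, 3, ("homemade_nova3",))


def classify_catalogue(
    catalogue: Mapping[str, FoodCode], ruleset: NovaRuleSet | None = None
) -> dict[str, NovaAssignment]:
    """Assign every catalogue code exactly one NOVA group."""
    ruleset = ruleset or NovaRuleSet.default()
    memo: dict[str, NovaAssignment] = {}
    for code in catalogue.values():
        classify_code(code, catalogue, ruleset, _memo=memo)
    return {cid: memo[cid] for cid in catalogue}


def _entry_energy(entry, catalogue) -> float:
    code = catalogue[entry.code_id] if not isinstance(entry, Mapping) else catalogue[entry["code_id"]]
    grams = entry.grams if not isinstance(entry, Mapping) else entry["grams"]
    return grams * code.energy_per_100g / 100.0


def nova4_energy_share(
    entries: Iterable,
    catalogue: Mapping[str, FoodCode],
    assignments: Mapping[str, NovaAssignment],
) -> float:
    """Percentage of total diary energy from NOVA 4 codes, in [0, 100].

    Invariant to splitting any entry into several entries with the same
    code and the same summed grams.
    """
    total = 0.0
    upf = 0.0
    for entry in entries:
        e = _entry_energy(entry, catalogue)
        total += e
        cid = entry["code_id"] if isinstance(entry, Mapping) else entry.code_id
        if assignments[cid].nova_group == 4:
            upf += e
    if total <= 0:
        raise UndefinedShareError("total diary energy is zero; NOVA 4 share undefined")
    return 100.0 * upf / total


def nova4_share_by_participant(
    diary: pd.DataFrame,
    catalogue: Mapping[str, FoodCode],
    assignments: Mapping[str, NovaAssignment],
) -> pd.Series:
    """Vectorised NOVA 4 energy share per participant from a long diary table.

    ``diary`` needs columns participant_id, code_id, grams.
    """
    energy100 = diary["code_id"].map(lambda c: catalogue[c].energy_per_100g)
    energy = diary["grams"].to_numpy() * energy100.to_numpy() / 100.0
    is4 = diary["code_id"].map(lambda c: assignments[c].nova_group == 4).to_numpy()
    frame = pd.DataFrame(
        {"participant_id": diary["participant_id"], "e": energy, "e4": energy * is4}
    )
    sums = frame.groupby("participant_id", sort=True).sum()
    if (sums["e"] <= 0).any():
        bad = sums.index[sums["e"] <= 0].tolist()
        raise UndefinedShareError(f"zero total energy for participants: {bad[:5]}")
    return 100.0 * sums["e4"] / sums["e"]


def assignments_frame(assignments: Mapping[str, NovaAssignment]) -> pd.DataFrame:
    """Tabular view of a classification (for assignments.csv)."""
    return pd.DataFrame(
        {
            "code_id": list(assignments),
            "nova_group": [a.nova_group for a in assignments.values()],
            "rule_trace": ["|".join(a.rule_trace) for a in assignments.values()],
        }
    )
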