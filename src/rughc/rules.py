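"""Classification rule configuration: triggers, scales and split maps as data.

The RUG-III/HC algorithm is a hierarchy of category *triggers* (boolean
conditions over clinical flags, therapy minutes, cognition and behaviour)
followed, within the triggered category, by a *split map* from (ADL band,
IADL band, auxiliary service counters) to a group code. Both layers are
configuration, shipped as an editable YAML file
(``rughc/data/rules_default.yaml``), because the trigger item lists are not
part of the algorithmic skeleton.

Validation enforces the structural invariants the classifier relies on:
exactly the seven canonical categories in hierarchy order, an always-true
terminal category, and a *total* split map (every reachable band combination
maps to a group of that category).
"""

from __future__ import annotations

import importlib.resources
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .errors import ConfigurationError
from .taxonomy import ADL_BANDS, CATEGORY_GROUPS, CATEGORY_ORDER, GROUP_CATEGORY

__all__ = ["AdlScale", "IadlScale", "Trigger", "SplitRule", "CategoryRule", "RuleConfig",
           "load_rules", "default_rules"]


class AdlScale(BaseModel):
    """Weighted-sum ADL scale with band cut-points A < B < C (< D implicit)."""

    items: list[str] = Field(min_length=1)
    code_min: int = 1
    code_max: int = 5
    weights: Optional[dict[str, float]] = None
    band_cutpoints: dict[str, float]

    @model_validator(mode="after")
    def _check(self) -> "AdlScale":
        if self.code_min > self.code_max:
            raise ValueError("adl_scale: code_min exceeds code_max")
        if self.weights is None:
            self.weights = {item: 1.0 for item in self.items}
        if set(self.weights) != set(self.items):
            raise ValueError("adl_scale: weights must cover exactly the configured items")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("adl_scale: negative item weight")
        if set(self.band_cutpoints) != {"A", "B", "C"}:
            raise ValueError("adl_scale: band_cutpoints must define upper bounds for A, B, C")
        a, b, c = (self.band_cutpoints[k] for k in ("A", "B", "C"))
        if not a < b < c:
            raise ValueError("adl_scale: band cut-points must be strictly increasing")
        return self

    def score(self, codes: dict[str, int]) -> float:
        return sum(self.weights[item] * codes[item] for item in self.items)

    def band(self, score: float) -> str:
        for band in ("A", "B", "C"):
            if score <= self.band_cutpoints[band]:
                return band
        return "D"

    @property
    def min_score(self) -> float:
        return sum(self.weights[i] for i in self.items) * self.code_min

    @property
    def max_score(self) -> float:
        return sum(self.weights[i] for i in self.items) * self.code_max


class IadlScale(BaseModel):
    """IADL difficulty: 'some' iff any item codes at/above the cut-point."""

    items: list[str] = Field(min_length=1)
    code_min: int = 0
    code_max: int = 3
    difficulty_cutpoint: int = 1

    @model_validator(mode="after")
    def _check(self) -> "IadlScale":
        if self.code_min > self.code_max:
            raise ValueError("iadl_scale: code_min exceeds code_max")
        if not (self.code_min < self.difficulty_cutpoint <= self.code_max):
            raise ValueError("iadl_scale: difficulty_cutpoint outside the code range")
        return self


class Trigger(BaseModel):
    """Category entry condition: OR over the conditions that are set."""

    always: bool = False
    therapy_minutes_min: Optional[float] = None
    clinical_any: Optional[list[str]] = None
    behaviour_any: Optional[list[str]] = None
    cognitive_performance_min: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "Trigger":
        if not self.always and all(
            v is None
            for v in (
                self.therapy_minutes_min,
                self.clinical_any,
                self.behaviour_any,
                self.cognitive_performance_min,
            )
        ):
            raise ValueError("trigger: no condition set and always is false")
        return self


class SplitRule(BaseModel):
    """One row of a category's split map; first matching rule wins."""

    group: str
    adl_bands: Optional[list[str]] = None
    iadl: Literal["none", "some", "any"] = "any"
    services_min: Optional[int] = None

    @field_validator("adl_bands")
    @classmethod
    def _bands(cls, v: Optional[list[str]]) -> Optional[list[str]]:
        if v is not None and not set(v) <= set(ADL_BANDS):
            raise ValueError(f"split rule: unknown ADL band in {v}")
        return v

    def matches(self, adl_band: str, iadl_band: str, n_services: int) -> bool:
        if self.adl_bands is not None and adl_band not in self.adl_bands:
            return False
        if self.iadl != "any" and iadl_band != self.iadl:
            return False
        if self.services_min is not None and n_services < self.services_min:
            return False
        return True


class CategoryRule(BaseModel):
    name: str
    trigger: Trigger
    splits: list[SplitRule] = Field(min_length=1)

    @model_validator(mode="after")
    def _check(self) -> "CategoryRule":
        if self.name not in CATEGORY_ORDER:
            raise ValueError(f"unknown category {self.name!r}")
        for rule in self.splits:
            if GROUP_CATEGORY.get(rule.group) != self.name:
                raise ValueError(
                    f"split map of {self.name}: group {rule.group!r} does not belong to it"
                )
        return self


class RuleConfig(BaseModel):
    adl_scale: AdlScale
    iadl_scale: IadlScale
    categories: list[CategoryRule]

    @model_validator(mode="after")
    def _check(self) -> "RuleConfig":
        names = [c.name for c in self.categories]
        if names != list(CATEGORY_ORDER):
            raise ValueError(
                "categories must be exactly the seven canonical categories in hierarchy order"
            )
        terminal = self.categories[-1]
        if not terminal.trigger.always:
            raise ValueError("ReducedPhysicalFunctions must have an always-true trigger")
        self._check_totality()
        return self

    # -- helpers ---------------------------------------------------------

    @property
    def extensive_services(self) -> list[str]:
        """Clinical flags counted by the extensive-services auxiliary counter."""
        for cat in self.categories:
            if cat.name == "ExtensiveServices":
                return list(cat.trigger.clinical_any or [])
        return []

    def category(self, name: str) -> CategoryRule:
        for cat in self.categories:
            if cat.name == name:
                return cat
        raise KeyError(name)

    def _check_totality(self) -> None:
        """Every reachable (band, IADL, service-count) combination must map to a group."""
        max_services = max(len(self.extensive_services), 1)
        for cat in self.categories:
            service_range = (
                range(1, max_services + 1) if cat.name == "ExtensiveServices" else (0,)
            )
            for band in ADL_BANDS:
                for iadl in ("none", "some"):
                    for n_svc in service_range:
                        if not any(r.matches(band, iadl, n_svc) for r in cat.splits):
                            raise ValueError(
                                f"split map of {cat.name} is not total: no rule for "
                                f"ADL band {band}, IADL {iadl}, services {n_svc}"
                            )
        covered = {r.group for cat in self.categories for r in cat.splits}
        for cat_name, groups in CATEGORY_GROUPS.items():
            missing = set(groups) - covered
            if missing:
                raise ValueError(f"groups {sorted(missing)} of {cat_name} unreachable")


def load_rules(path: str) -> RuleConfig:
    """Load and validate a rule configuration from a YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return RuleConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def default_rules() -> RuleConfig:
    """The rule configuration shipped with the package."""
    text = (
        importlib.resources.files("rughc").joinpath("data/rules_default.yaml").read_text("utf-8")
    )
    return RuleConfig.model_validate(yaml.safe_load(text))
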