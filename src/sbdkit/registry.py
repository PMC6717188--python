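"""Classification-rule registry.

Rules are shipped as package data (``data/clp_rules.yaml``) and loaded into an
immutable :class:`RuleRegistry`.  Three calculation methods are supported:

threshold
    Sum the fractions of ingredients carrying the (class, category) hazard
    that are present at or above the generic cut-off; classify the mixture
    when the sum reaches the generic concentration limit (GCL).
additivity
    Reciprocal-weighted acute-toxicity combination: 100/ATE_mix equals the sum
    of c_i/ATE_i over relevant components, and ATE_mix is banded into a
    category.
summation
    Aquatic-hazard rows: M-factor-weighted component sums compared to a 25 %
    threshold, evaluated per category from most to least severe.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .core import RegistryError, scope_of

__all__ = [
    "AteBand",
    "SummationComponent",
    "ClassificationRule",
    "RuleRegistry",
    "load_rule_registry",
    "DEFAULT_REGISTRY_PATH",
]

DEFAULT_REGISTRY_PATH = Path(__file__).parent / "data" / "clp_rules.yaml"


class AteBand(BaseModel):
    """One acute-toxicity category band: classified when ATE_mix <= max_ate."""

    model_config = ConfigDict(frozen=True)

    category: str
    max_ate: float = Field(gt=0)
    h_code: Optional[str] = None

    @field_validator("category", mode="before")
    @classmethod
    def _cat(cls, v):
        return str(v)


class SummationComponent(BaseModel):
    """One term of a summation row: which (class, category) counts, at what weight."""

    model_config = ConfigDict(frozen=True)

    hazard_class: str
    category: str
    multiplier: float = Field(default=1.0, gt=0)
    m_factor: Literal["acute", "chronic", "none"] = "none"

    @field_validator("category", mode="before")
    @classmethod
    def _cat(cls, v):
        return str(v)


class ClassificationRule(BaseModel):
    model_config = ConfigDict(frozen=True)

    hazard_class: str
    category: str  # "*" for additivity rules governing a whole class
    method: Literal["threshold", "additivity", "summation"]
    generic_cutoff: float = Field(gt=0, le=100)
    gcl: Optional[float] = None
    h_code: Optional[str] = None
    # additivity
    route: Optional[str] = None
    bands: tuple[AteBand, ...] = ()
    conversion_values: dict[str, float] = Field(default_factory=dict)
    # summation
    threshold: Optional[float] = None
    components: tuple[SummationComponent, ...] = ()

    @field_validator("category", mode="before")
    @classmethod
    def _cat(cls, v):
        return str(v)

    @model_validator(mode="after")
    def _method_fields(self):
        if self.method == "threshold":
            if self.gcl is None:
                raise ValueError("threshold rule requires a gcl")
            if not (0 < self.generic_cutoff <= self.gcl <= 100):
                raise ValueError(
                    f"threshold rule must satisfy 0 < cutoff <= gcl <= 100, "
                    f"got cutoff={self.generic_cutoff}, gcl={self.gcl}"
                )
        elif self.method == "additivity":
            if not self.bands:
                raise ValueError("additivity rule requires category bands")
            edges = [b.max_ate for b in self.bands]
            if edges != sorted(edges):
                raise ValueError("additivity bands must have increasing max_ate")
        elif self.method == "summation":
            if self.threshold is None or not self.components:
                raise ValueError("summation rule requires threshold and components")
        return self

    @property
    def key(self) -> tuple[str, str]:
        return (self.hazard_class, self.category)

    @property
    def scope(self):
        return scope_of(self.hazard_class)


#: Severity order for summation cascades: lower index = more severe category.
_CATEGORY_ORDER = {"1": 0, "1A": 0, "1B": 1, "2": 2, "3": 3, "4": 4}


def _category_rank(category: str) -> int:
    return _CATEGORY_ORDER.get(category, 99)


class RuleRegistry:
    """Immutable lookup of classification rules keyed by (hazard_class, category)."""

    def __init__(self, rules: Iterable[ClassificationRule], version: str = "custom"):
        self.version = version
        self._rules: dict[tuple[str, str], ClassificationRule] = {}
        for rule in rules:
            if rule.key in self._rules:
                raise RegistryError(f"duplicate registry entry for {rule.key}")
            self._rules[rule.key] = rule

    def __len__(self) -> int:
        return len(self._rules)

    def __iter__(self):
        return iter(self._rules.values())

    def get(self, hazard_class: str, category: str) -> Optional[ClassificationRule]:
        """Rule governing this (class, category); additivity rules match any category."""
        rule = self._rules.get((hazard_class, str(category)))
        if rule is None:
            rule = self._rules.get((hazard_class, "*"))
        return rule

    def require(self, hazard_class: str, category: str) -> ClassificationRule:
        rule = self.get(hazard_class, category)
        if rule is None:
            raise RegistryError(f"no rule registered for ({hazard_class}, {category})")
        return rule

    def rules_for_class(self, hazard_class: str) -> list[ClassificationRule]:
        """All rules of a hazard class, most severe category first."""
        rules = [r for r in self._rules.values() if r.hazard_class == hazard_class]
        return sorted(rules, key=lambda r: _category_rank(r.category))

    def hazard_classes(self) -> set[str]:
        return {r.hazard_class for r in self._rules.values()}


def _parse_rule(raw: dict) -> ClassificationRule:
    raw = dict(raw)
    params = raw.pop("parameters", {}) or {}
    merged = {**raw, **params}
    try:
        return ClassificationRule(**merged)
    except (TypeError, ValueError) as exc:
        raise RegistryError(f"invalid rule entry {raw.get('hazard_class')!r}: {exc}") from exc


def load_rule_registry(path: Optional[Union[str, Path]] = None) -> RuleRegistry:
    """Load the shipped registry, optionally merged with an override file.

    Override entries replace shipped entries with the same (class, category)
    key and may add new ones.  Duplicates *within* one file raise
    :class:`RegistryError`.
    """
    with open(DEFAULT_REGISTRY_PATH) as fh:
        doc = yaml.safe_load(fh)
    rules = {r.key: r for r in map(_parse_rule, doc["rules"])}
    if len(rules) != len(doc["rules"]):
        raise RegistryError("duplicate (class, category) entries in shipped registry")
    version = doc.get("registry_version", "unversioned")

    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh)
        entries = override.get("rules", []) if isinstance(override, dict) else override
        seen: set[tuple[str, str]] = set()
        for raw in entries:
            rule = _parse_rule(raw)
            if rule.key in seen:
                raise RegistryError(f"duplicate (class, category) entry {rule.key} in override")
            seen.add(rule.key)
            rules[rule.key] = rule
        version = f"{version}+override"

    return RuleRegistry(rules.values(), version=version)
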