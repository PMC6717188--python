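"""Screening mixture self-classification and hazard-driven reformulation guidance.

The engine applies calculation-based mixture rules to a formulation's
ingredient hazard profiles: threshold rules (generic cut-off + generic
concentration limit), the acute-toxicity additivity formula, and the aquatic
summation method.  Classification is conservative: range-valued fractions are
evaluated at their upper bound.

On top of classification, :func:`suggest_adjustments` inverts the rules to
tell a product developer how far each hazardous ingredient must be reduced
for each assigned hazard to disappear, and :func:`iterate_screening` replays
a sequence of composition edits, tracking the hazard trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import (
    ClassificationError,
    Formulation,
    HazardEntry,
    Ingredient,
    Scope,
)
from .registry import ClassificationRule, RuleRegistry, _category_rank

__all__ = [
    "TriggerIngredient",
    "Driver",
    "AssignedHazard",
    "RuleEvaluation",
    "MixtureClassification",
    "AdjustmentSuggestion",
    "CompositionEdit",
    "ScreeningIteration",
    "classify_mixture",
    "suggest_adjustments",
    "iterate_screening",
]

#: Unknown-hazard fraction at or above which the classification carries a
#: data-gap warning (no hazard is assigned for it).
UNKNOWN_FRACTION_WARN = 10.0

_VERIFY_EPS = 1e-9


class TriggerIngredient(BaseModel):
    model_config = ConfigDict(frozen=True)

    id: str
    concentration: float  # % w/w actually used (interval upper bound)
    weight: float = 1.0  # M-factor x multiplier for summation; 1 otherwise


class Driver(BaseModel):
    """Provenance of one assigned hazard: which rule fired, on which ingredients."""

    model_config = ConfigDict(frozen=True)

    method: str  # threshold | additivity | summation | experimental
    triggering_ingredients: tuple[TriggerIngredient, ...] = ()
    value: Optional[float] = None  # summed % (threshold/summation) or ATE_mix
    threshold: Optional[float] = None
    provenance: str = "clp_screening"


class AssignedHazard(BaseModel):
    model_config = ConfigDict(frozen=True)

    entry: HazardEntry
    driver: Driver


class RuleEvaluation(BaseModel):
    """Record of one rule evaluation, triggered or not (full decision trace)."""

    model_config = ConfigDict(frozen=True)

    hazard_class: str
    category: str
    method: str
    relevant: tuple[TriggerIngredient, ...] = ()
    value: Optional[float] = None
    threshold: Optional[float] = None
    triggered: bool = False


class MixtureClassification(BaseModel):
    model_config = ConfigDict(frozen=True)

    formulation_id: str
    assigned: tuple[AssignedHazard, ...] = ()
    evaluations: tuple[RuleEvaluation, ...] = ()
    count_H: int = 0
    count_ENV: int = 0
    unknown_fraction: float = 0.0
    not_classifiable: bool = False
    warnings: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _counts(self):
        n_h = sum(1 for a in self.assigned if a.entry.scope is Scope.H)
        n_env = len(self.assigned) - n_h
        if (self.count_H, self.count_ENV) != (n_h, n_env):
            raise ValueError("hazard counts inconsistent with assigned list")
        return self

    @property
    def assigned_classes(self) -> set[str]:
        return {a.entry.hazard_class for a in self.assigned}

    @property
    def hazard_count(self) -> int:
        """Distinct assigned hazard classes (category variants counted once)."""
        return len(self.assigned_classes)

    def has(self, hazard_class: str, category: Optional[str] = None) -> bool:
        return any(
            a.entry.hazard_class == hazard_class
            and (category is None or a.entry.category == category)
            for a in self.assigned
        )


def _conc(ing: Ingredient) -> float:
    # worst-case convention: interval upper bound
    return ing.mass_fraction.upper


def _m_factor(ing: Ingredient, which: str) -> float:
    if which == "acute":
        return ing.m_factor_acute
    if which == "chronic":
        return ing.m_factor_chronic
    return 1.0


def _ate_for(ing: Ingredient, entry: HazardEntry, rule: ClassificationRule) -> float:
    ate = ing.ate.get(rule.route or "oral")
    if ate is not None:
        return ate
    conv = rule.conversion_values.get(entry.category)
    if conv is None:
        raise ClassificationError(
            f"ingredient {ing.id!r} declares {entry.hazard_class} category "
            f"{entry.category} but no ATE and no conversion value is registered"
        )
    return conv


def _check_rules(ingredients: Sequence[Ingredient], registry: RuleRegistry) -> None:
    for ing in ingredients:
        for h in ing.hazards:
            if registry.get(h.hazard_class, h.category) is None:
                raise ClassificationError(
                    f"no classification rule for ({h.hazard_class}, {h.category}) "
                    f"carried by ingredient {ing.id!r}"
                )


def _eval_threshold(
    rule: ClassificationRule, key: tuple[str, str], ingredients: Sequence[Ingredient]
) -> RuleEvaluation:
    relevant = []
    for ing in ingredients:
        if any(h.key() == key for h in ing.hazards) and _conc(ing) >= rule.generic_cutoff:
            relevant.append(TriggerIngredient(id=ing.id, concentration=_conc(ing)))
    total = sum(t.concentration for t in relevant)
    return RuleEvaluation(
        hazard_class=key[0],
        category=key[1],
        method="threshold",
        relevant=tuple(relevant),
        value=total,
        threshold=rule.gcl,
        triggered=bool(relevant) and total >= rule.gcl,
    )


def _eval_additivity(
    rule: ClassificationRule, hazard_class: str, ingredients: Sequence[Ingredient]
) -> tuple[RuleEvaluation, Optional[str]]:
    relevant, inv_sum = [], 0.0
    for ing in ingredients:
        entries = [h for h in ing.hazards if h.hazard_class == hazard_class]
        if not entries or _conc(ing) < rule.generic_cutoff:
            continue
        ate = min(_ate_for(ing, e, rule) for e in entries)
        relevant.append(TriggerIngredient(id=ing.id, concentration=_conc(ing)))
        inv_sum += _conc(ing) / ate
    worst = rule.bands[-1].max_ate
    ate_mix = 100.0 / inv_sum if inv_sum > 0 else float("inf")
    category = next((b.category for b in rule.bands if ate_mix <= b.max_ate), None)
    evaluation = RuleEvaluation(
        hazard_class=hazard_class,
        category=category if category is not None else "none",
        method="additivity",
        relevant=tuple(relevant),
        value=ate_mix if inv_sum > 0 else None,
        threshold=worst,
        triggered=category is not None,
    )
    return evaluation, category


def _eval_summation_row(
    rule: ClassificationRule, ingredients: Sequence[Ingredient]
) -> RuleEvaluation:
    relevant = []
    total = 0.0
    for ing in ingredients:
        if _conc(ing) < rule.generic_cutoff:
            continue
        weight = 0.0
        for comp in rule.components:
            if any(h.key() == (comp.hazard_class, comp.category) for h in ing.hazards):
                weight += comp.multiplier * _m_factor(ing, comp.m_factor)
        if weight > 0:
            relevant.append(
                TriggerIngredient(id=ing.id, concentration=_conc(ing), weight=weight)
            )
            total += weight * _conc(ing)
    return RuleEvaluation(
        hazard_class=rule.hazard_class,
        category=rule.category,
        method="summation",
        relevant=tuple(relevant),
        value=total,
        threshold=rule.threshold,
        triggered=bool(relevant) and total >= rule.threshold,
    )


def classify_mixture(f: Formulation, registry: RuleRegistry) -> MixtureClassification:
    """CLP-style calculation-based self-classification of a mixture.

    Returns the assigned hazards together with the full decision trace
    (every rule evaluated, its relevant ingredients, sum/ATE and threshold),
    so that a non-triggering ingredient that was nevertheless taken into
    account remains visible.
    """
    classifiable = [i for i in f.ingredients if not i.unknown_hazard]
    _check_rules(classifiable, registry)

    warnings: list[str] = []
    unknown = f.unknown_fraction
    not_classifiable = bool(f.ingredients) and not classifiable
    if not_classifiable:
        warnings.append("no ingredient has usable hazard data; mixture not classifiable")
    elif unknown >= UNKNOWN_FRACTION_WARN:
        warnings.append(
            f"hazards unknown for {unknown:.3g}% of the formulation (>= "
            f"{UNKNOWN_FRACTION_WARN:g}%); screening covers the known fraction only"
        )

    evaluations: list[RuleEvaluation] = []
    assigned: list[AssignedHazard] = []

    # deterministic rule order, independent of ingredient order
    threshold_keys: list[tuple[str, str]] = []
    additivity_classes: list[str] = []
    summation_classes: list[str] = []
    for ing in classifiable:
        for h in ing.hazards:
            rule = registry.require(h.hazard_class, h.category)
            if rule.method == "threshold" and h.key() not in threshold_keys:
                threshold_keys.append(h.key())
            elif rule.method == "additivity" and h.hazard_class not in additivity_classes:
                additivity_classes.append(h.hazard_class)
            elif rule.method == "summation" and h.hazard_class not in summation_classes:
                summation_classes.append(h.hazard_class)
    threshold_keys.sort(key=lambda k: (k[0], _category_rank(k[1])))
    additivity_classes.sort()
    summation_classes.sort()

    for key in threshold_keys:
        rule = registry.require(*key)
        ev = _eval_threshold(rule, key, classifiable)
        evaluations.append(ev)
        if ev.triggered:
            assigned.append(
                AssignedHazard(
                    entry=HazardEntry(
                        hazard_class=key[0], category=key[1], h_code=rule.h_code
                    ),
                    driver=Driver(
                        method="threshold",
                        triggering_ingredients=ev.relevant,
                        value=ev.value,
                        threshold=ev.threshold,
                    ),
                )
            )

    for cls in additivity_classes:
        rule = registry.require(cls, "*")
        ev, category = _eval_additivity(rule, cls, classifiable)
        evaluations.append(ev)
        if category is not None:
            h_code = next((b.h_code for b in rule.bands if b.category == category), None)
            assigned.append(
                AssignedHazard(
                    entry=HazardEntry(hazard_class=cls, category=category, h_code=h_code),
                    driver=Driver(
                        method="additivity",
                        triggering_ingredients=ev.relevant,
                        value=ev.value,
                        threshold=ev.threshold,
                    ),
                )
            )

    for cls in summation_classes:
        hit = False
        for rule in registry.rules_for_class(cls):  # most severe category first
            ev = _eval_summation_row(rule, classifiable)
            evaluations.append(ev)
            if ev.triggered and not hit:
                hit = True
                assigned.append(
                    AssignedHazard(
                        entry=HazardEntry(
                            hazard_class=cls, category=rule.category, h_code=rule.h_code
                        ),
                        driver=Driver(
                            method="summation",
                            triggering_ingredients=ev.relevant,
                            value=ev.value,
                            threshold=ev.threshold,
                        ),
                    )
                )

    n_h = sum(1 for a in assigned if a.entry.scope is Scope.H)
    return MixtureClassification(
        formulation_id=f.id,
        assigned=tuple(assigned),
        evaluations=tuple(evaluations),
        count_H=n_h,
        count_ENV=len(assigned) - n_h,
        unknown_fraction=unknown,
        not_classifiable=not_classifiable,
        warnings=tuple(warnings),
    )


class AdjustmentSuggestion(BaseModel):
    """Reduce ``ingredient_id`` strictly below ``bound`` (% w/w) and the listed
    hazard classes are no longer assigned (others' fractions held fixed)."""

    model_config = ConfigDict(frozen=True)

    ingredient_id: str
    bound: float
    hazards_removed: tuple[str, ...]  # cumulative: everything gone below bound
    hazards_remaining: tuple[str, ...]
    joint: bool = False  # other ingredients co-drive >=1 removed hazard


def _threshold_bound(
    registry: RuleRegistry,
    classification: MixtureClassification,
    hazard_class: str,
    ing_id: str,
) -> Optional[tuple[float, bool]]:
    """Bound below which no assigned category of a threshold class survives."""
    bounds, joint = [], False
    for a in classification.assigned:
        if a.entry.hazard_class != hazard_class or a.driver.method != "threshold":
            continue
        rule = registry.require(hazard_class, a.entry.category)
        ids = [t.id for t in a.driver.triggering_ingredients]
        if ing_id not in ids:
            return None  # this category stays regardless of the ingredient
        others = sum(
            t.concentration for t in a.driver.triggering_ingredients if t.id != ing_id
        )
        if others >= rule.gcl:
            return None
        joint = joint or others > 0
        bounds.append(max(rule.generic_cutoff, rule.gcl - others))
    if not bounds:
        return None
    return min(bounds), joint


def _additivity_bound(
    registry: RuleRegistry,
    classification: MixtureClassification,
    hazard_class: str,
    ing_id: str,
    f: Formulation,
) -> Optional[tuple[float, bool]]:
    rule = registry.require(hazard_class, "*")
    assigned = [
        a
        for a in classification.assigned
        if a.entry.hazard_class == hazard_class and a.driver.method == "additivity"
    ]
    if not assigned:
        return None
    trigger = assigned[0].driver.triggering_ingredients
    if ing_id not in [t.id for t in trigger]:
        return None
    limit = 100.0 / rule.bands[-1].max_ate  # classified while sum c/ATE >= limit
    others_inv, ate_self = 0.0, None
    for t in trigger:
        ing = f.ingredient(t.id)
        entries = [h for h in ing.hazards if h.hazard_class == hazard_class]
        ate = min(_ate_for(ing, e, rule) for e in entries)
        if t.id == ing_id:
            ate_self = ate
        else:
            others_inv += t.concentration / ate
    if others_inv >= limit:
        return None
    bound = max(rule.generic_cutoff, ate_self * (limit - others_inv))
    return bound, len(trigger) > 1


def _summation_bound(
    registry: RuleRegistry,
    hazard_class: str,
    ing_id: str,
    f: Formulation,
) -> Optional[tuple[float, bool]]:
    """Bound below which no summation row of the class reaches its threshold."""
    classifiable = [i for i in f.ingredients if not i.unknown_hazard]
    bounds, joint = [], False
    for rule in registry.rules_for_class(hazard_class):
        ev = _eval_summation_row(rule, classifiable)
        mine = next((t for t in ev.relevant if t.id == ing_id), None)
        others = sum(t.weight * t.concentration for t in ev.relevant if t.id != ing_id)
        if mine is None:
            if ev.triggered:
                return None  # row fires independently of this ingredient
            continue
        if others >= rule.threshold:
            return None
        joint = joint or others > 0
        bounds.append(
            max(rule.generic_cutoff, (rule.threshold - others) / mine.weight)
        )
    if not bounds:
        return None
    return min(bounds), joint


def suggest_adjustments(
    f: Formulation, registry: RuleRegistry, verify: bool = True
) -> list[AdjustmentSuggestion]:
    """Per-ingredient concentration bounds at which assigned hazards cease.

    Bounds are solved analytically from the rule that assigned each hazard and
    (by default) verified by re-classifying the formulation with the
    ingredient just below the bound.  Bounds are open: the hazard disappears
    strictly below the bound, mirroring the ">= triggers" convention.
    """
    classification = classify_mixture(f, registry)
    if not classification.assigned:
        return []
    all_classes = sorted(classification.assigned_classes)

    suggestions: list[AdjustmentSuggestion] = []
    for ing in sorted(f.ingredients, key=lambda i: i.id):
        if ing.unknown_hazard or not ing.hazards:
            continue
        per_class: dict[str, tuple[float, bool]] = {}
        for cls in all_classes:
            rule = next(iter(registry.rules_for_class(cls)), None)
            if rule is None:
                continue
            if rule.method == "threshold":
                res = _threshold_bound(registry, classification, cls, ing.id)
            elif rule.method == "additivity":
                res = _additivity_bound(registry, classification, cls, ing.id, f)
            else:
                res = _summation_bound(registry, cls, ing.id, f)
            if res is not None:
                per_class[cls] = res
        if not per_class:
            continue

        for bound in sorted({b for b, _ in per_class.values()}, reverse=True):
            removed = tuple(sorted(c for c, (b, _) in per_class.items() if b >= bound))
            remaining = tuple(sorted(set(all_classes) - set(removed)))
            joint = any(j for c, (b, j) in per_class.items() if b >= bound)
            if verify:
                probe = classify_mixture(
                    f.set_fraction(ing.id, max(bound - _VERIFY_EPS, 0.0)), registry
                )
                leftover = probe.assigned_classes & set(removed)
                if leftover:
                    raise ClassificationError(
                        f"analytic bound {bound}% for {ing.id!r} failed verification; "
                        f"still assigned: {sorted(leftover)}"
                    )
            suggestions.append(
                AdjustmentSuggestion(
                    ingredient_id=ing.id,
                    bound=bound,
                    hazards_removed=removed,
                    hazards_remaining=remaining,
                    joint=joint,
                )
            )
    return suggestions


@dataclass(frozen=True)
class CompositionEdit:
    """One reformulation step: fraction changes and ingredient add/remove."""

    label: str = ""
    set_fractions: dict = field(default_factory=dict)  # ingredient id -> new fraction
    add: tuple = ()  # new Ingredient objects
    remove: tuple = ()  # ingredient ids
    new_id: Optional[str] = None  # rename the resulting formulation

    def apply(self, f: Formulation) -> Formulation:
        out = f
        for ing_id in self.remove:
            out = out.remove_ingredient(ing_id)
        for ing_id, fraction in self.set_fractions.items():
            out = out.set_fraction(ing_id, fraction)
        for ing in self.add:
            out = out.add_ingredient(ing)
        if self.new_id:
            out = out.model_copy(update={"id": self.new_id, "label": self.label or self.new_id})
        return out


class ScreeningIteration(BaseModel):
    model_config = ConfigDict(frozen=True)

    formulation_id: str
    classification: MixtureClassification
    hazards_added: tuple[str, ...] = ()  # vs previous iteration, as "class:category"
    hazards_removed: tuple[str, ...] = ()


def _entry_keys(c: MixtureClassification) -> set[str]:
    return {f"{a.entry.hazard_class}:{a.entry.category}" for a in c.assigned}


def iterate_screening(
    f: Formulation, edits: Iterable[CompositionEdit], registry: RuleRegistry
) -> list[ScreeningIteration]:
    """Classify a formulation, then each successive edited version.

    Returns the classification trajectory with per-iteration hazard deltas;
    an edit producing an invalid composition raises an error naming the
    iteration.
    """
    current = f
    trajectory = [
        ScreeningIteration(
            formulation_id=current.id,
            classification=classify_mixture(current, registry),
        )
    ]
    for k, edit in enumerate(edits, start=1):
        try:
            current = edit.apply(current)
        except (ValueError, KeyError) as exc:
            raise ClassificationError(f"iteration {k} ({edit.label or 'unnamed'}): {exc}") from exc
        classification = classify_mixture(current, registry)
        prev_keys = _entry_keys(trajectory[-1].classification)
        keys = _entry_keys(classification)
        trajectory.append(
            ScreeningIteration(
                formulation_id=current.id,
                classification=classification,
                hazards_added=tuple(sorted(keys - prev_keys)),
                hazards_removed=tuple(sorted(prev_keys - keys)),
            )
        )
    return trajectory
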