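"""Tiered integrated testing strategy (ITS) for aquatic hazard.

Tier 1 screens acute aquatic toxicity with three bioassays (Daphnia magna
immobilisation, algal growth inhibition, Aliivibrio fischeri luminescence):
an EC50 below 1 mg/L for any species classifies the formulation Acute 1 and
stops the strategy.  Tier 2 uses the chronic Daphnia magna reproduction NOEC:
<= 0.01 mg/L -> Chronic 1, (0.01, 0.1] -> Chronic 2, (0.1, 1] -> Chronic 3.
A NOEC above 1 mg/L sends the formulation to tier 3, where bacterial
genotoxicity screens (umu test, SOS Chromotest) flag residual concern via
their induction ratios; no aquatic class is assigned there.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from .core import (
    Assay,
    BioassayResult,
    ClassificationError,
    EndpointType,
    HazardEntry,
    Scope,
)
from .screening import AssignedHazard, Driver, MixtureClassification, TriggerIngredient

__all__ = ["AquaticClass", "ITSOutcome", "run_its", "merge_with_screening"]

TIER1_ASSAYS = (Assay.OECD202_DAPHNIA, Assay.OECD201_ALGAE, Assay.ISO11348_ALIIVIBRIO)
TIER3_ASSAYS = (Assay.UMU_ISO13829, Assay.SOS_CHROMOTEST)

#: EC50 below which any single species classifies the mixture Acute 1 (mg/L).
ACUTE1_EC50_LIMIT = 1.0
#: NOEC band edges (mg/L): <= .01 Chronic 1; (.01, .1] Chronic 2; (.1, 1] Chronic 3.
CHRONIC_EDGES = (0.01, 0.1, 1.0)
#: Default induction-ratio positivity cut-off for the genotoxicity screens.
GENOTOX_INDUCTION_THRESHOLD = 1.5


class AquaticClass(str, enum.Enum):
    NONE = "none"
    ACUTE1 = "Acute1"
    CHRONIC1 = "Chronic1"
    CHRONIC2 = "Chronic2"
    CHRONIC3 = "Chronic3"


class ITSOutcome(BaseModel):
    model_config = ConfigDict(frozen=True)

    tier_reached: int  # 1 | 2 | 3
    aquatic_class: AquaticClass
    genotoxicity_alert: Optional[bool] = None  # None = not evaluated (tiers 1-2)
    status: str = "complete"  # complete | incomplete
    evidence: tuple[BioassayResult, ...] = ()
    trace: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _tier_consistency(self):
        if self.status == "incomplete":
            return self
        if self.aquatic_class is AquaticClass.ACUTE1 and self.tier_reached != 1:
            raise ValueError("Acute 1 is a tier-1 terminal state")
        if (
            self.aquatic_class
            in (AquaticClass.CHRONIC1, AquaticClass.CHRONIC2, AquaticClass.CHRONIC3)
            and self.tier_reached != 2
        ):
            raise ValueError("Chronic classes are tier-2 terminal states")
        if self.genotoxicity_alert is not None and self.tier_reached != 3:
            raise ValueError("genotoxicity is evaluated only at tier 3")
        return self


def _collect(
    results: Iterable[BioassayResult], duplicate_policy: str
) -> dict[Assay, BioassayResult]:
    by_assay: dict[Assay, list[BioassayResult]] = {}
    for r in results:
        by_assay.setdefault(r.assay, []).append(r)
    out: dict[Assay, BioassayResult] = {}
    for assay, rs in by_assay.items():
        if len(rs) > 1:
            if duplicate_policy != "min":
                raise ClassificationError(
                    f"{len(rs)} results for assay {assay.value}; supply one endpoint "
                    "per assay or enable the 'min' aggregation policy"
                )
            rs = [min(rs, key=lambda r: r.value)]
        out[assay] = rs[0]
    return out


def run_its(
    results: Iterable[BioassayResult],
    genotox_threshold: float = GENOTOX_INDUCTION_THRESHOLD,
    duplicate_policy: str = "error",
) -> ITSOutcome:
    """Walk the tiered strategy over a set of bioassay endpoints.

    Missing mandatory data never passes silently: absent tier-1 assays (or an
    absent chronic NOEC when tier 2 is reached) yield an ``incomplete``
    outcome naming the gap.
    """
    by_assay = _collect(results, duplicate_policy)
    trace: list[str] = []

    missing = [a.value for a in TIER1_ASSAYS if a not in by_assay]
    if missing:
        return ITSOutcome(
            tier_reached=1,
            aquatic_class=AquaticClass.NONE,
            status="incomplete",
            trace=(f"tier 1 incomplete: missing {', '.join(missing)}",),
        )

    tier1 = [by_assay[a] for a in TIER1_ASSAYS]
    worst = min(tier1, key=lambda r: r.value)
    trace.append(
        f"tier 1: min EC50 = {worst.value:g} mg/L ({worst.assay.value}, {worst.species})"
    )
    if worst.value < ACUTE1_EC50_LIMIT:
        trace.append(f"EC50 < {ACUTE1_EC50_LIMIT:g} mg/L for at least one species -> Acute 1")
        return ITSOutcome(
            tier_reached=1,
            aquatic_class=AquaticClass.ACUTE1,
            evidence=tuple(tier1),
            trace=tuple(trace),
        )
    trace.append(f"no EC50 < {ACUTE1_EC50_LIMIT:g} mg/L -> proceed to tier 2")

    noec = by_assay.get(Assay.OECD211_DAPHNIA_REPRO)
    if noec is None:
        return ITSOutcome(
            tier_reached=2,
            aquatic_class=AquaticClass.NONE,
            status="incomplete",
            evidence=tuple(tier1),
            trace=tuple(trace) + ("tier 2 incomplete: missing OECD211_daphnia_repro NOEC",),
        )
    e1, e2, e3 = CHRONIC_EDGES
    trace.append(f"tier 2: NOEC = {noec.value:g} mg/L ({noec.species})")
    chronic = None
    if noec.value <= e1:
        chronic = AquaticClass.CHRONIC1
    elif noec.value <= e2:
        chronic = AquaticClass.CHRONIC2
    elif noec.value <= e3:
        chronic = AquaticClass.CHRONIC3
    if chronic is not None:
        trace.append(f"NOEC banding -> {chronic.value}")
        return ITSOutcome(
            tier_reached=2,
            aquatic_class=chronic,
            evidence=tuple(tier1) + (noec,),
            trace=tuple(trace),
        )
    trace.append(f"NOEC > {e3:g} mg/L -> proceed to tier 3")

    tier3 = [by_assay[a] for a in TIER3_ASSAYS if a in by_assay]
    alert = any(r.value >= genotox_threshold for r in tier3) if tier3 else False
    if tier3:
        ratios = ", ".join(f"{r.assay.value}={r.value:g}" for r in tier3)
        trace.append(
            f"tier 3: induction ratios {ratios} vs threshold {genotox_threshold:g} -> "
            f"{'genotoxicity alert' if alert else 'no alert'}"
        )
    else:
        trace.append("tier 3: no genotoxicity screens supplied -> no alert")
    return ITSOutcome(
        tier_reached=3,
        aquatic_class=AquaticClass.NONE,
        genotoxicity_alert=alert,
        evidence=tuple(tier1) + (noec,) + tuple(tier3),
        trace=tuple(trace),
    )


_CLASS_TO_ENTRY = {
    AquaticClass.ACUTE1: HazardEntry(hazard_class="aquatic_acute", category="1", h_code="H400"),
    AquaticClass.CHRONIC1: HazardEntry(hazard_class="aquatic_chronic", category="1", h_code="H410"),
    AquaticClass.CHRONIC2: HazardEntry(hazard_class="aquatic_chronic", category="2", h_code="H411"),
    AquaticClass.CHRONIC3: HazardEntry(hazard_class="aquatic_chronic", category="3", h_code="H412"),
}


def merge_with_screening(
    c: MixtureClassification, o: ITSOutcome
) -> MixtureClassification:
    """Fold the experimental aquatic class into a screening classification.

    An aquatic hazard observed on the whole formulation adds (or replaces)
    the corresponding calculated entry; experimental provenance wins.  The
    operation is idempotent.  A tier-3 genotoxicity alert is carried on the
    screening side as a warning, not a counted hazard.
    """
    assigned = list(c.assigned)
    warnings = list(c.warnings)
    if o.aquatic_class is not AquaticClass.NONE:
        entry = _CLASS_TO_ENTRY[o.aquatic_class]
        assigned = [a for a in assigned if a.entry.hazard_class != entry.hazard_class]
        assigned.append(
            AssignedHazard(
                entry=entry,
                driver=Driver(
                    method="experimental",
                    triggering_ingredients=(
                        TriggerIngredient(id=c.formulation_id, concentration=100.0),
                    ),
                    provenance="experimental",
                ),
            )
        )
    if o.genotoxicity_alert:
        note = "tier-3 genotoxicity alert (umu/SOS induction); not counted as a hazard"
        if note not in warnings:
            warnings.append(note)
    n_h = sum(1 for a in assigned if a.entry.scope is Scope.H)
    return c.model_copy(
        update={
            "assigned": tuple(assigned),
            "count_H": n_h,
            "count_ENV": len(assigned) - n_h,
            "warnings": tuple(warnings),
        }
    )
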