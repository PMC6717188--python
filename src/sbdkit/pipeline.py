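"""End-to-end orchestration: screening -> testing strategy -> safety -> MCDA.

A :class:`FrameworkRun` replays the stepwise assessment over one or more
candidate formulations, applying a go/adjust/discard gate after the hazard
stages (by default an experimentally confirmed Acute 1 discards the
candidate), and finishes with a sustainability ranking of the survivors
against any supplied benchmark scorecards.
"""

from __future__ import annotations

import hashlib
import json
from typing import Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .core import BioassayResult, Formulation, SbdError
from .its import AquaticClass, ITSOutcome, merge_with_screening, run_its
from .mcda import IndicatorScore, SustainabilityResult, aggregate_and_rank, score_pillars
from .registry import RuleRegistry, load_rule_registry
from .safety import ExposureAssessment, SafetyAssessment, assess_safety, band_exposure
from .screening import (
    AdjustmentSuggestion,
    MixtureClassification,
    classify_mixture,
    suggest_adjustments,
)

__all__ = ["GateDecision", "FrameworkConfig", "FormulationRecord", "FrameworkRun",
           "run_framework", "render_report"]

GateDecision = str  # "proceed" | "adjust" | "discard"

#: Default gate policy keyed by the experimental aquatic class.
DEFAULT_GATE_POLICY: dict[str, GateDecision] = {
    AquaticClass.ACUTE1.value: "discard",
    AquaticClass.CHRONIC1.value: "adjust",
    AquaticClass.CHRONIC2.value: "proceed",
    AquaticClass.CHRONIC3.value: "proceed",
    AquaticClass.NONE.value: "proceed",
}


class FrameworkConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    gate_policy: dict[str, GateDecision] = Field(
        default_factory=lambda: dict(DEFAULT_GATE_POLICY)
    )
    genotox_threshold: float = 1.5
    duplicate_policy: str = "error"
    rmms_applied: bool = False
    safety_matrix: Optional[tuple[tuple[str, ...], ...]] = None
    pillar_weights: Optional[dict[str, float]] = None
    seed: int = 0

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class FormulationRecord(BaseModel):
    """All stage outputs for one formulation, in execution order."""

    model_config = ConfigDict(frozen=True)

    formulation_id: str
    screening: MixtureClassification
    suggestions: tuple[AdjustmentSuggestion, ...] = ()
    its: Optional[ITSOutcome] = None
    merged: Optional[MixtureClassification] = None
    exposure: Optional[ExposureAssessment] = None
    safety: Optional[SafetyAssessment] = None
    gate: GateDecision = "proceed"
    gate_reason: str = ""


class FrameworkRun(BaseModel):
    model_config = ConfigDict(frozen=True)

    records: tuple[FormulationRecord, ...]
    sustainability: tuple[SustainabilityResult, ...] = ()
    provenance: dict[str, str] = Field(default_factory=dict)


def run_framework(
    formulations: Sequence[Formulation],
    bioassays: Mapping[str, Sequence[BioassayResult]],
    scorecards: Optional[Mapping[str, Sequence]] = None,
    config: Optional[FrameworkConfig] = None,
    registry: Optional[RuleRegistry] = None,
) -> FrameworkRun:
    """Run screening, the tiered testing strategy, safety banding and MCDA.

    ``bioassays`` and ``scorecards`` are keyed by formulation/product id;
    scorecard keys that match no formulation (e.g. a conventional benchmark
    product) enter the ranking with their own environmental indicator.
    A discarded formulation has no records past its gate.
    """
    config = config or FrameworkConfig()
    registry = registry or load_rule_registry()
    scorecards = scorecards or {}

    records: list[FormulationRecord] = []
    survivors: list[tuple[Formulation, SafetyAssessment]] = []
    for f in formulations:
        try:
            screening = classify_mixture(f, registry)
            suggestions = tuple(suggest_adjustments(f, registry))
        except SbdError as exc:
            raise SbdError(f"screening stage failed for {f.id!r}: {exc}") from exc

        if f.id not in bioassays:
            records.append(
                FormulationRecord(
                    formulation_id=f.id,
                    screening=screening,
                    suggestions=suggestions,
                    gate="adjust",
                    gate_reason="tiered testing incomplete: no bioassay table supplied",
                )
            )
            continue
        try:
            its = run_its(
                bioassays[f.id],
                genotox_threshold=config.genotox_threshold,
                duplicate_policy=config.duplicate_policy,
            )
        except SbdError as exc:
            raise SbdError(f"testing-strategy stage failed for {f.id!r}: {exc}") from exc

        if its.status == "incomplete":
            records.append(
                FormulationRecord(
                    formulation_id=f.id,
                    screening=screening,
                    suggestions=suggestions,
                    its=its,
                    gate="adjust",
                    gate_reason="; ".join(its.trace) or "tiered testing incomplete",
                )
            )
            continue

        gate = config.gate_policy.get(its.aquatic_class.value, "proceed")
        if gate != "proceed":
            records.append(
                FormulationRecord(
                    formulation_id=f.id,
                    screening=screening,
                    suggestions=suggestions,
                    its=its,
                    gate=gate,
                    gate_reason=f"experimental aquatic class {its.aquatic_class.value}",
                )
            )
            continue

        merged = merge_with_screening(screening, its)
        exposure = band_exposure(f, rmms_applied=config.rmms_applied)
        safety = assess_safety(merged, exposure, matrix=config.safety_matrix)
        records.append(
            FormulationRecord(
                formulation_id=f.id,
                screening=screening,
                suggestions=suggestions,
                its=its,
                merged=merged,
                exposure=exposure,
                safety=safety,
                gate="proceed",
                gate_reason=f"aquatic class {its.aquatic_class.value}",
            )
        )
        survivors.append((f, safety))

    products: list[tuple[str, dict[str, float]]] = []
    for f, safety in survivors:
        card = [IndicatorScore(**s) if isinstance(s, dict) else s
                for s in scorecards.get(f.id, [])]
        if card or safety is not None:
            try:
                products.append((f.id, score_pillars(card, safety=safety)))
            except SbdError:
                pass  # formulation without a usable scorecard stays unranked
    known = {f.id for f in formulations}
    for pid in sorted(scorecards):
        if pid not in known:
            card = [IndicatorScore(**s) if isinstance(s, dict) else s for s in scorecards[pid]]
            products.append((pid, score_pillars(card)))
    sustainability = tuple(aggregate_and_rank(products)) if products else ()

    return FrameworkRun(
        records=tuple(records),
        sustainability=sustainability,
        provenance={
            "config_hash": config.content_hash(),
            "registry_version": registry.version,
            "matrix_version": records[0].safety.matrix_version
            if records and records[0].safety
            else (config.safety_matrix and "override" or "sbdkit-matrix-1"),
            "seed": str(config.seed),
        },
    )


def render_report(run: FrameworkRun, format: str = "json") -> str:
    """Deterministic report of a framework run (``json`` or ``markdown``)."""
    if format == "json":
        return json.dumps(run.model_dump(mode="json"), indent=2, sort_keys=True) + "\n"
    if format != "markdown":
        raise SbdError(f"unknown report format {format!r} (expected json or markdown)")

    lines = ["# Safe-by-Design framework run", ""]
    for rec in run.records:
        lines.append(f"## Formulation {rec.formulation_id}")
        c = rec.merged or rec.screening
        hazard_list = (
            ", ".join(
                f"{a.entry.hazard_class} cat {a.entry.category} ({a.driver.provenance})"
                for a in c.assigned
            )
            or "none"
        )
        lines.append(f"- assigned hazards: {hazard_list}")
        for s in rec.suggestions:
            lines.append(
                f"- reduce {s.ingredient_id} below {s.bound:g}% to remove: "
                + ", ".join(s.hazards_removed)
            )
        if rec.its is not None:
            lines.append(
                f"- testing strategy: tier {rec.its.tier_reached}, "
                f"aquatic class {rec.its.aquatic_class.value} ({rec.its.status})"
            )
        if rec.safety is not None:
            lines.append(
                f"- exposure {rec.exposure.band.value}, safety band {rec.safety.band.value}"
            )
        lines.append(f"- gate: **{rec.gate}** ({rec.gate_reason})")
        lines.append("")
    if run.sustainability:
        lines.append("## Sustainability ranking")
        for r in run.sustainability:
            pillars = ", ".join(f"{p}={v:g}" for p, v in sorted(r.pillar_scores.items()))
            lines.append(f"{r.rank}. {r.product_id}: overall {r.overall:g} ({pillars})")
        lines.append("")
    lines.append(f"provenance: {json.dumps(run.provenance, sort_keys=True)}")
    return "\n".join(lines) + "\n"
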