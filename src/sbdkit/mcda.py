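"""Multi-criteria sustainability scoring and ranking.

Indicators under four pillars (environmental, economic, social/ethical/legal,
technological) are scored on a five-class satisfaction scale — excellent 5,
good 4, moderate 3, poor 2, bad 1 — and aggregated by weighted arithmetic
mean, first within pillars and then across them, yielding an overall
sustainability score per product and a ranking of innovative against
conventional products.  The environmental pillar can be auto-populated from
the control-banding safety assessment via the same class-to-score mapping.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .core import ConfigurationError
from .safety import SafetyAssessment, SafetyBand

__all__ = [
    "PILLARS",
    "SATISFACTION_SCORES",
    "IndicatorScore",
    "SustainabilityResult",
    "score_pillars",
    "aggregate_and_rank",
    "safety_band_score",
]

PILLARS = ("environmental", "economic", "social_ethical_legal", "technological")

#: Satisfaction class <-> numeric score bijection.
SATISFACTION_SCORES = {"excellent": 5, "good": 4, "moderate": 3, "poor": 2, "bad": 1}
_SCORE_CLASSES = {v: k for k, v in SATISFACTION_SCORES.items()}


def safety_band_score(band: Union[SafetyBand, str]) -> int:
    """Map a control-banding safety band to the 1-5 indicator score."""
    return SATISFACTION_SCORES[SafetyBand(band).value]


class IndicatorScore(BaseModel):
    """One scored indicator (e.g. market_size, regulatory_barriers, compatibility)."""

    model_config = ConfigDict(frozen=True)

    pillar: str
    indicator: str
    score: int = Field(ge=1, le=5)
    satisfaction: str = ""
    weight: float = Field(default=1.0, ge=0.0)

    @model_validator(mode="before")
    @classmethod
    def _class_score(cls, data):
        if isinstance(data, dict):
            sat, score = data.get("satisfaction"), data.get("score")
            if score is None and sat:
                data["score"] = SATISFACTION_SCORES.get(str(sat))
                if data["score"] is None:
                    raise ValueError(f"unknown satisfaction class {sat!r}")
        return data

    @model_validator(mode="after")
    def _bijection(self):
        expected = _SCORE_CLASSES[self.score]
        if not self.satisfaction:
            object.__setattr__(self, "satisfaction", expected)
        elif self.satisfaction != expected:
            raise ValueError(
                f"satisfaction {self.satisfaction!r} does not match score {self.score}"
            )
        if self.pillar not in PILLARS:
            raise ValueError(f"unknown pillar {self.pillar!r} (expected one of {PILLARS})")
        return self


class SustainabilityResult(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    pillar_scores: dict[str, float]
    pillar_weights: dict[str, float]
    overall: float = Field(ge=1.0, le=5.0)
    rank: Optional[int] = None
    tie_break: str = "overall, then environmental-first pillar comparison, then id"

    @model_validator(mode="after")
    def _bounds(self):
        for pillar, score in self.pillar_scores.items():
            if not 1.0 <= score <= 5.0:
                raise ValueError(f"pillar {pillar!r} score {score} outside [1, 5]")
        return self


def _weighted_mean(pairs: Sequence[tuple[float, float]]) -> float:
    total_w = sum(w for _, w in pairs)
    if total_w <= 0:
        raise ConfigurationError("weights must be non-negative with a positive sum")
    return sum(s * w for s, w in pairs) / total_w


def score_pillars(
    scorecard: Iterable[IndicatorScore],
    safety: Optional[SafetyAssessment] = None,
) -> dict[str, float]:
    """Weighted-mean pillar scores from an indicator scorecard.

    If the environmental pillar has no indicators and a safety assessment is
    supplied, it is auto-populated from the safety band (excellent -> 5 ...
    bad -> 1).  Every pillar must end up with at least one indicator.
    """
    scorecard = [s if isinstance(s, IndicatorScore) else IndicatorScore(**s) for s in scorecard]
    by_pillar: dict[str, list[IndicatorScore]] = {p: [] for p in PILLARS}
    for s in scorecard:
        by_pillar[s.pillar].append(s)
    if not by_pillar["environmental"] and safety is not None:
        by_pillar["environmental"].append(
            IndicatorScore(
                pillar="environmental",
                indicator="safety_band",
                score=safety_band_score(safety.band),
            )
        )
    scores: dict[str, float] = {}
    for pillar in PILLARS:
        entries = by_pillar[pillar]
        if not entries:
            raise ConfigurationError(f"pillar {pillar!r} has no indicators")
        if all(e.weight == 0 for e in entries):
            raise ConfigurationError(f"pillar {pillar!r} has all-zero weights")
        scores[pillar] = _weighted_mean([(e.score, e.weight) for e in entries])
    return scores


def aggregate_and_rank(
    products: Sequence[tuple[str, Mapping[str, float]]],
    pillar_weights: Optional[Mapping[str, float]] = None,
) -> list[SustainabilityResult]:
    """Overall sustainability score per product and descending ranking.

    All products must be scored on the same pillar set; weights default to
    equal.  Ties on the overall score are broken by comparing pillar scores
    in the order of :data:`PILLARS` (environmental first), then by id, and the
    tie-break is declared on each result.
    """
    if not products:
        return []
    pillar_set = tuple(sorted(products[0][1]))
    for pid, scores in products:
        if tuple(sorted(scores)) != pillar_set:
            raise ConfigurationError(
                f"product {pid!r} is scored on a different pillar set"
            )
    if pillar_weights is None:
        pillar_weights = {p: 1.0 for p in pillar_set}
    if set(pillar_weights) != set(pillar_set):
        raise ConfigurationError("pillar_weights must cover exactly the scored pillars")
    if any(w < 0 for w in pillar_weights.values()) or sum(pillar_weights.values()) <= 0:
        raise ConfigurationError("weights must be non-negative with a positive sum")

    results = []
    for pid, scores in products:
        overall = _weighted_mean([(scores[p], pillar_weights[p]) for p in pillar_set])
        results.append(
            SustainabilityResult(
                product_id=pid,
                pillar_scores=dict(scores),
                pillar_weights={p: pillar_weights[p] for p in pillar_set},
                overall=overall,
            )
        )

    def sort_key(r: SustainabilityResult):
        pillar_vec = tuple(-r.pillar_scores.get(p, 0.0) for p in PILLARS)
        return (-r.overall, pillar_vec, r.product_id)

    results.sort(key=sort_key)
    return [r.model_copy(update={"rank": i + 1}) for i, r in enumerate(results)]
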