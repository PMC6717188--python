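"""Exposure banding, control-banding safety matrix and PEC/PNEC risk ratio.

Occupational exposure during application of a consolidant is proxied by the
% w/w of hazardous volatile components: below 1 % it is negligible (as is any
scenario where all recommended risk management measures are applied), up to
10 % low, up to 50 % medium, above 50 % high.  The safety level combines the
number of assigned H + ENV hazards (five bands) with the exposure band (four
bands) in a 5x4 lookup matrix.  For the post-application phase, a
deterministic risk characterisation ratio RCR = PEC/PNEC is provided, with
PNEC derived from the most sensitive ecotoxicological endpoint divided by an
assessment factor.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .core import (
    BioassayResult,
    ConfigurationError,
    EndpointType,
    Formulation,
    SbdError,
)
from .screening import MixtureClassification

__all__ = [
    "ExposureBand",
    "SafetyBand",
    "ExposureAssessment",
    "SafetyAssessment",
    "RiskRatio",
    "band_exposure",
    "band_from_fraction",
    "hazardous_volatile_fraction",
    "hazard_class_index",
    "assess_safety",
    "risk_ratio",
    "DEFAULT_MATRIX",
    "render_matrix",
]


class ExposureBand(str, enum.Enum):
    NEGLIGIBLE = "negligible"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class SafetyBand(str, enum.Enum):
    EXCELLENT = "excellent"
    GOOD = "good"
    MODERATE = "moderate"
    POOR = "poor"
    BAD = "bad"


_EXPOSURE_INDEX = {b: i + 1 for i, b in enumerate(ExposureBand)}
_SAFETY_RANK = {b: i for i, b in enumerate(SafetyBand)}  # 0 best .. 4 worst

#: Exposure band edges in % w/w of hazardous volatile components.
EXPOSURE_EDGES = (1.0, 10.0, 50.0)

#: Hazard-count bands -> hazard class index 1..5: {0}, {1-2}, {3-4}, {5-6}, {>=7}.
HAZARD_COUNT_EDGES = (0, 2, 4, 6)

#: Default 5x4 control-banding matrix (rows: hazard class index 1..5,
#: columns: exposure negligible..high).  Only the two corners are fixed by
#: the banding scheme (<=2 hazards & <=10% volatiles -> excellent; >6 hazards
#: & >50% -> bad); the interior interpolates monotonically.
DEFAULT_MATRIX: tuple[tuple[SafetyBand, ...], ...] = tuple(
    tuple(SafetyBand(x) for x in row)
    for row in (
        ("excellent", "excellent", "good", "good"),
        ("excellent", "excellent", "good", "moderate"),
        ("good", "good", "moderate", "poor"),
        ("moderate", "moderate", "poor", "poor"),
        ("moderate", "poor", "poor", "bad"),
    )
)
DEFAULT_MATRIX_VERSION = "sbdkit-matrix-1"


class ExposureAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    hazardous_volatile_fraction: float = Field(ge=0.0, le=100.0)
    rmms_applied: bool
    band: ExposureBand


class SafetyAssessment(BaseModel):
    model_config = ConfigDict(frozen=True)

    formulation_id: str
    hazard_count: int = Field(ge=0)
    hazard_class_index: int = Field(ge=1, le=5)
    exposure_index: int = Field(ge=1, le=4)
    band: SafetyBand
    matrix_version: str = DEFAULT_MATRIX_VERSION


class RiskRatio(BaseModel):
    model_config = ConfigDict(frozen=True)

    pec: float = Field(gt=0)
    pnec: float = Field(gt=0)
    rcr: float = Field(gt=0)
    assessment_factor: float = Field(gt=0)
    safe: bool
    boundary: bool = False  # rcr exactly 1


def band_from_fraction(fraction: float, rmms_applied: bool) -> ExposureBand:
    """Exposure band for a hazardous-volatile % w/w.

    All recommended RMMs applied -> negligible regardless of concentration;
    otherwise negligible below 1 %, low on [1, 10], medium on (10, 50],
    high above 50 %.
    """
    if rmms_applied or fraction < EXPOSURE_EDGES[0]:
        return ExposureBand.NEGLIGIBLE
    if fraction <= EXPOSURE_EDGES[1]:
        return ExposureBand.LOW
    if fraction <= EXPOSURE_EDGES[2]:
        return ExposureBand.MEDIUM
    return ExposureBand.HIGH


def hazardous_volatile_fraction(f: Formulation) -> float:
    """Summed % w/w (interval upper bounds) of volatile ingredients carrying
    at least one hazard (unknown-hazard volatiles count conservatively)."""
    return sum(
        i.mass_fraction.upper
        for i in f.ingredients
        if i.is_volatile and (i.hazards or i.unknown_hazard)
    )


def band_exposure(f: Formulation, rmms_applied: bool) -> ExposureAssessment:
    fraction = min(hazardous_volatile_fraction(f), 100.0)
    return ExposureAssessment(
        hazardous_volatile_fraction=fraction,
        rmms_applied=rmms_applied,
        band=band_from_fraction(fraction, rmms_applied),
    )


def hazard_class_index(hazard_count: int) -> int:
    """Map a hazard count to the matrix row: {0}->1, {1-2}->2, {3-4}->3,
    {5-6}->4, {>=7}->5."""
    for idx, edge in enumerate(HAZARD_COUNT_EDGES):
        if hazard_count <= edge:
            return idx + 1
    return 5


def _validate_matrix(matrix: Sequence[Sequence[SafetyBand]]) -> None:
    if len(matrix) != 5 or any(len(row) != 4 for row in matrix):
        raise ConfigurationError("safety matrix must be 5 rows x 4 columns")
    for i in range(5):
        for j in range(4):
            cell = _SAFETY_RANK[SafetyBand(matrix[i][j])]
            if i + 1 < 5 and _SAFETY_RANK[SafetyBand(matrix[i + 1][j])] < cell:
                raise ConfigurationError("safety matrix improves with more hazards")
            if j + 1 < 4 and _SAFETY_RANK[SafetyBand(matrix[i][j + 1])] < cell:
                raise ConfigurationError("safety matrix improves with higher exposure")


def assess_safety(
    c: MixtureClassification,
    e: ExposureAssessment,
    matrix: Optional[Sequence[Sequence[str]]] = None,
    matrix_version: Optional[str] = None,
) -> SafetyAssessment:
    """Combine (merged) hazard count and exposure band in the lookup matrix.

    ``hazard_count`` counts distinct assigned hazard classes (a category
    upgrade of an already-counted class does not add).
    """
    if matrix is None:
        table, version = DEFAULT_MATRIX, DEFAULT_MATRIX_VERSION
    else:
        table = tuple(tuple(SafetyBand(x) for x in row) for row in matrix)
        _validate_matrix(table)
        version = matrix_version or "override"
    count = c.hazard_count
    row = hazard_class_index(count)
    col = _EXPOSURE_INDEX[e.band]
    return SafetyAssessment(
        formulation_id=c.formulation_id,
        hazard_count=count,
        hazard_class_index=row,
        exposure_index=col,
        band=table[row - 1][col - 1],
        matrix_version=version,
    )


def risk_ratio(
    pec: float,
    endpoints: Iterable[BioassayResult],
    chronic_available: Optional[bool] = None,
    assessment_factor: Optional[float] = None,
) -> RiskRatio:
    """Deterministic post-application risk characterisation: RCR = PEC/PNEC.

    PNEC is the most sensitive concentration endpoint divided by an
    assessment factor — 1000 for acute-only data, 10 when a chronic NOEC is
    available (both overridable).
    """
    if pec <= 0:
        raise SbdError(f"PEC must be positive, got {pec}")
    endpoints = list(endpoints)
    values = [
        r.value for r in endpoints if r.endpoint_type is not EndpointType.INDUCTION_RATIO
    ]
    if not values:
        raise SbdError("risk ratio requires at least one concentration endpoint")
    if chronic_available is None:
        chronic_available = any(
            r.endpoint_type is EndpointType.NOEC for r in endpoints
        )
    if assessment_factor is None:
        assessment_factor = 10.0 if chronic_available else 1000.0
    pnec = min(values) / assessment_factor
    rcr = pec / pnec
    return RiskRatio(
        pec=pec,
        pnec=pnec,
        rcr=rcr,
        assessment_factor=assessment_factor,
        safe=rcr < 1.0,
        boundary=rcr == 1.0,
    )


def render_matrix(
    assessment: Optional[SafetyAssessment] = None,
    matrix: Sequence[Sequence[SafetyBand]] = DEFAULT_MATRIX,
) -> str:
    """Plain-text rendering of the control-banding matrix, optionally with the
    assessed formulation's cell marked."""
    col_heads = [b.value for b in ExposureBand]
    row_heads = ["0", "1-2", "3-4", "5-6", ">=7"]
    width = 12
    lines = ["hazards \\ exposure".ljust(20) + "".join(h.ljust(width) for h in col_heads)]
    for i, row in enumerate(matrix):
        cells = []
        for j, cell in enumerate(row):
            mark = (
                assessment is not None
                and assessment.hazard_class_index == i + 1
                and assessment.exposure_index == j + 1
            )
            text = f"[{cell.value}]" if mark else cell.value
            cells.append(text.ljust(width))
        lines.append(row_heads[i].ljust(20) + "".join(cells))
    return "\n".join(lines)
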