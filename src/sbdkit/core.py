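"""Domain types for Safe-by-Design formulation assessment.

The central objects are :class:`Formulation` (an ingredient list with mass
fractions in % w/w and per-ingredient GHS/CLP hazard profiles) and
:class:`BioassayResult` (an ecotoxicological endpoint from one of the assays
used by the tiered testing strategy).  Mass fractions may be single values or
closed intervals, as they typically appear on safety data sheets (SDS);
screening is conservative and works on the interval upper bound.
"""

from __future__ import annotations

import enum
from typing import Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Scope",
    "HazardEntry",
    "MassFraction",
    "Ingredient",
    "Formulation",
    "Assay",
    "EndpointType",
    "BioassayResult",
    "ENV_HAZARD_CLASSES",
    "SbdError",
    "SchemaError",
    "CompositionError",
    "RegistryError",
    "ClassificationError",
    "ConfigurationError",
]


class SbdError(Exception):
    """Base class for all package errors."""


class SchemaError(SbdError):
    """Input does not validate against the documented schema."""


class CompositionError(SbdError):
    """Mass fractions are individually or jointly out of range."""


class RegistryError(SbdError):
    """Malformed or duplicated classification-rule registry entries."""


class ClassificationError(SbdError):
    """The classification engine cannot proceed (e.g. missing rule)."""


class ConfigurationError(SbdError):
    """Malformed configuration (lookup matrix, weights, gate policy)."""


class Scope(str, enum.Enum):
    """Whether a hazard class concerns human health (H) or the environment (ENV)."""

    H = "H"
    ENV = "ENV"


#: Hazard classes that count toward the environmental (ENV) tally; everything
#: else in the registry is a health (H) hazard.
ENV_HAZARD_CLASSES = frozenset({"aquatic_acute", "aquatic_chronic"})


def scope_of(hazard_class: str) -> Scope:
    return Scope.ENV if hazard_class in ENV_HAZARD_CLASSES else Scope.H


class HazardEntry(BaseModel):
    """One CLP hazard classification of a substance (class + category + H-code)."""

    model_config = ConfigDict(frozen=True)

    hazard_class: str
    category: str
    h_code: Optional[str] = None

    @field_validator("category", mode="before")
    @classmethod
    def _coerce_category(cls, v):
        return str(v)

    @property
    def scope(self) -> Scope:
        return scope_of(self.hazard_class)

    def key(self) -> tuple:
        return (self.hazard_class, self.category)


class MassFraction(BaseModel):
    """A % w/w content, either a single value or a closed interval [lower, upper]."""

    model_config = ConfigDict(frozen=True)

    lower: float = Field(ge=0.0, le=100.0)
    upper: float = Field(ge=0.0, le=100.0)

    @model_validator(mode="after")
    def _ordered(self):
        if self.lower > self.upper:
            raise ValueError(
                f"mass fraction interval lower ({self.lower}) exceeds upper ({self.upper})"
            )
        return self

    @classmethod
    def coerce(cls, value: Union["MassFraction", float, int, list, tuple, dict]) -> "MassFraction":
        if isinstance(value, MassFraction):
            return value
        if isinstance(value, dict):
            return cls(**value)
        if isinstance(value, (list, tuple)):
            if len(value) != 2:
                raise ValueError("interval mass fraction needs exactly [lower, upper]")
            return cls(lower=float(value[0]), upper=float(value[1]))
        return cls(lower=float(value), upper=float(value))

    @property
    def is_interval(self) -> bool:
        return self.lower != self.upper

    @property
    def nominal(self) -> float:
        """Midpoint (equals the value itself for single-valued fractions)."""
        return 0.5 * (self.lower + self.upper)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.is_interval:
            return f"{self.lower}-{self.upper}%"
        return f"{self.upper}%"


class Ingredient(BaseModel):
    """One component of a formulation with its SDS-derived hazard profile.

    ``ate`` maps an exposure route (currently ``oral``) to an acute toxicity
    estimate in mg/kg bw.  ``m_factor_acute`` / ``m_factor_chronic`` are the
    CLP multiplying factors for highly toxic aquatic components (>= 1).
    An ingredient whose SDS is unavailable cannot be classified; its fraction
    is booked as unknown-hazard instead.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    name: str = ""
    mass_fraction: MassFraction
    hazards: tuple[HazardEntry, ...] = ()
    ate: dict[str, float] = Field(default_factory=dict)
    m_factor_acute: float = Field(default=1.0, ge=1.0)
    m_factor_chronic: float = Field(default=1.0, ge=1.0)
    is_nanoform: bool = False
    is_volatile: bool = False
    sds_available: bool = True

    @field_validator("mass_fraction", mode="before")
    @classmethod
    def _coerce_fraction(cls, v):
        return MassFraction.coerce(v)

    @field_validator("hazards", mode="before")
    @classmethod
    def _coerce_hazards(cls, v):
        return tuple(v)

    @field_validator("ate")
    @classmethod
    def _positive_ate(cls, v):
        for route, value in v.items():
            if value <= 0:
                raise ValueError(f"ATE for route {route!r} must be positive, got {value}")
        return v

    @property
    def unknown_hazard(self) -> bool:
        """True when the ingredient cannot enter classification (no SDS)."""
        return not self.sds_available

    @property
    def is_hazardous(self) -> bool:
        return bool(self.hazards) and not self.unknown_hazard

    def with_fraction(self, fraction) -> "Ingredient":
        return self.model_copy(update={"mass_fraction": MassFraction.coerce(fraction)})


#: Tolerance (percentage points) on the nominal composition sum; SDS ranges
#: and rounding routinely push the midpoint total slightly past 100.
DEFAULT_COMPOSITION_TOLERANCE = 0.5


class Formulation(BaseModel):
    """An identified mixture: ingredient list with % w/w fractions."""

    model_config = ConfigDict(frozen=True)

    id: str
    label: str = ""
    ingredients: tuple[Ingredient, ...] = ()
    composition_tolerance: float = Field(default=DEFAULT_COMPOSITION_TOLERANCE, ge=0.0)

    @field_validator("ingredients", mode="before")
    @classmethod
    def _coerce_ingredients(cls, v):
        return tuple(v)

    @model_validator(mode="after")
    def _composition(self):
        ids = [i.id for i in self.ingredients]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate ingredient ids in formulation {self.id!r}")
        total = sum(i.mass_fraction.nominal for i in self.ingredients)
        if total > 100.0 + self.composition_tolerance:
            raise ValueError(
                f"nominal composition of {self.id!r} sums to {total:.2f}% "
                f"(> 100 + {self.composition_tolerance})"
            )
        return self

    @property
    def unknown_fraction(self) -> float:
        """% w/w covered by ingredients whose hazards cannot be assessed."""
        return sum(i.mass_fraction.nominal for i in self.ingredients if i.unknown_hazard)

    def ingredient(self, ingredient_id: str) -> Ingredient:
        for ing in self.ingredients:
            if ing.id == ingredient_id:
                return ing
        raise KeyError(f"no ingredient {ingredient_id!r} in formulation {self.id!r}")

    def set_fraction(self, ingredient_id: str, fraction) -> "Formulation":
        """Return a copy with one ingredient's fraction replaced."""
        new = tuple(
            ing.with_fraction(fraction) if ing.id == ingredient_id else ing
            for ing in self.ingredients
        )
        self.ingredient(ingredient_id)  # raise KeyError if absent
        return self.model_copy(update={"ingredients": new})

    def add_ingredient(self, ingredient: Ingredient) -> "Formulation":
        return Formulation(
            id=self.id,
            label=self.label,
            ingredients=self.ingredients + (ingredient,),
            composition_tolerance=self.composition_tolerance,
        )

    def remove_ingredient(self, ingredient_id: str) -> "Formulation":
        self.ingredient(ingredient_id)
        return self.model_copy(
            update={
                "ingredients": tuple(i for i in self.ingredients if i.id != ingredient_id)
            }
        )


class Assay(str, enum.Enum):
    """Bioassays used by the tiered aquatic-hazard testing strategy."""

    OECD202_DAPHNIA = "OECD202_daphnia"
    OECD201_ALGAE = "OECD201_algae"
    ISO11348_ALIIVIBRIO = "ISO11348_aliivibrio"
    OECD211_DAPHNIA_REPRO = "OECD211_daphnia_repro"
    UMU_ISO13829 = "UMU_ISO13829"
    SOS_CHROMOTEST = "SOS_chromotest"


class EndpointType(str, enum.Enum):
    EC50 = "EC50"
    NOEC = "NOEC"
    INDUCTION_RATIO = "induction_ratio"


#: Endpoint admissible for each assay: EC50 for the three acute (tier-1)
#: tests, NOEC for the chronic Daphnia reproduction test, induction ratio for
#: the two bacterial genotoxicity screens.
ASSAY_ENDPOINTS: dict[Assay, EndpointType] = {
    Assay.OECD202_DAPHNIA: EndpointType.EC50,
    Assay.OECD201_ALGAE: EndpointType.EC50,
    Assay.ISO11348_ALIIVIBRIO: EndpointType.EC50,
    Assay.OECD211_DAPHNIA_REPRO: EndpointType.NOEC,
    Assay.UMU_ISO13829: EndpointType.INDUCTION_RATIO,
    Assay.SOS_CHROMOTEST: EndpointType.INDUCTION_RATIO,
}

#: Default species per assay, used when a table omits the species column.
ASSAY_SPECIES: dict[Assay, str] = {
    Assay.OECD202_DAPHNIA: "Daphnia magna",
    Assay.OECD201_ALGAE: "Pseudokirchneriella subcapitata",
    Assay.ISO11348_ALIIVIBRIO: "Aliivibrio fischeri",
    Assay.OECD211_DAPHNIA_REPRO: "Daphnia magna",
    Assay.UMU_ISO13829: "Salmonella typhimurium TA1535/pSK1002",
    Assay.SOS_CHROMOTEST: "Escherichia coli PQ37",
}


class BioassayResult(BaseModel):
    """One ecotoxicological endpoint (mg/L; dimensionless for induction ratios)."""

    model_config = ConfigDict(frozen=True)

    assay: Assay
    species: str = ""
    endpoint_type: EndpointType
    value: float = Field(gt=0.0)
    units: str = "mg/L"

    @model_validator(mode="after")
    def _admissible(self):
        expected = ASSAY_ENDPOINTS[self.assay]
        if self.endpoint_type != expected:
            raise ValueError(
                f"assay {self.assay.value} takes endpoint {expected.value}, "
                f"got {self.endpoint_type.value}"
            )
        if self.endpoint_type == EndpointType.INDUCTION_RATIO:
            if self.units not in ("", "dimensionless", "-"):
                raise ValueError("induction ratios are dimensionless")
        elif self.units != "mg/L":
            raise ValueError(f"endpoint units must be mg/L, got {self.units!r}")
        if not self.species:
            object.__setattr__(self, "species", ASSAY_SPECIES[self.assay])
        return self
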