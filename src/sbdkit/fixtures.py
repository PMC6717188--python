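"""Synthetic inputs: a reference consolidant case and simulated bioassays.

Everything any downstream stage needs can be generated here, reproducibly
from a seed: the three-formulation reference case (an initial formulation IF
whose ingredient 2 carries acute oral toxicity, eye irritation, skin
sensitisation and a chronic aquatic hazard; two adjusted formulations AF1 and
AF2 at 0.70 % and 0.01 % w/w of that ingredient), simulated dose-response
bioassay tables for the tiered testing strategy, and random formulations for
property-based testing.

Acute endpoints are simulated from a two-parameter log-logistic curve

    response(c) = 1 / (1 + (c / EC50)^slope)

(relative to an untreated control) with additive Gaussian replicate noise,
and the EC50 re-estimated by least-squares.  The chronic NOEC is derived
from the simulated reproduction table as the highest tested concentration
whose mean response stays within an effect threshold of the control — a
pragmatic stand-in for the hypothesis-testing NOEC of the reproduction test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import (
    Assay,
    BioassayResult,
    EndpointType,
    Formulation,
    HazardEntry,
    Ingredient,
)
from .io import write_bioassays, write_formulation
from .registry import RuleRegistry

__all__ = [
    "DoseResponseCurve",
    "EC50Fit",
    "simulate_bioassay",
    "estimate_noec",
    "CaseStudyBundle",
    "make_case_study_fixtures",
    "random_formulation",
    "write_case_study",
]

#: Relative effect vs control below which a chronic test concentration is
#: treated as "no observed effect".
NOEC_EFFECT_THRESHOLD = 0.10


@dataclass(frozen=True)
class DoseResponseCurve:
    """Generative description of one simulated bioassay."""

    ec50: float  # mg/L, true value
    slope: float = 2.0
    noise_sd: float = 0.02
    concentrations: tuple[float, ...] = ()
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.ec50 <= 0:
            raise ValueError("EC50 must be positive")
        if not self.concentrations:
            object.__setattr__(
                self,
                "concentrations",
                tuple(np.geomspace(self.ec50 / 10.0, self.ec50 * 10.0, 7)),
            )
        if len(self.concentrations) < 5:
            raise ValueError("need at least 5 test concentrations")
        concs = self.concentrations
        if not (min(concs) < self.ec50 < max(concs)):
            raise ValueError("test concentrations must span the true EC50")


def _log_logistic(c, ec50, slope):
    return 1.0 / (1.0 + (c / ec50) ** slope)


def _simulate_table(curve: DoseResponseCurve) -> pd.DataFrame:
    """Replicate responses (control-normalised) incl. untreated controls at c=0."""
    rng = np.random.default_rng(curve.seed)
    rows = []
    for conc in (0.0,) + tuple(curve.concentrations):
        mean = 1.0 if conc == 0.0 else _log_logistic(conc, curve.ec50, curve.slope)
        for rep in range(curve.replicates):
            resp = mean + rng.normal(0.0, curve.noise_sd)
            resp = float(np.clip(resp, 0.0, 1.0 + 3.0 * curve.noise_sd))
            rows.append({"concentration": conc, "replicate": rep, "response": resp})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EC50Fit:
    status: str  # converged | non_converged
    ec50: Optional[float] = None
    slope: Optional[float] = None
    ci95: Optional[tuple[float, float]] = None


def fit_ec50(table: pd.DataFrame) -> EC50Fit:
    """Least-squares log-logistic fit; flat or inverted curves do not converge."""
    data = table[table["concentration"] > 0]
    c = data["concentration"].to_numpy(float)
    y = data["response"].to_numpy(float)
    means = data.groupby("concentration")["response"].mean()
    # a usable curve must actually descend
    if means.iloc[-1] >= means.iloc[0] - 0.1 or means.min() > 0.7 or means.max() < 0.3:
        return EC50Fit(status="non_converged")
    try:
        popt, pcov = curve_fit(
            _log_logistic,
            c,
            y,
            p0=(float(np.exp(np.mean(np.log(c)))), 1.0),
            bounds=([c.min() / 100.0, 0.05], [c.max() * 100.0, 50.0]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError):
        return EC50Fit(status="non_converged")
    ec50, slope = float(popt[0]), float(popt[1])
    se = float(np.sqrt(max(pcov[0, 0], 0.0)))
    return EC50Fit(
        status="converged",
        ec50=ec50,
        slope=slope,
        ci95=(max(ec50 - 1.96 * se, 0.0), ec50 + 1.96 * se),
    )


def simulate_bioassay(curve: DoseResponseCurve) -> tuple[pd.DataFrame, EC50Fit]:
    """Simulate a replicate dose-response table and re-estimate the EC50."""
    table = _simulate_table(curve)
    return table, fit_ec50(table)


def estimate_noec(
    table: pd.DataFrame, effect_threshold: float = NOEC_EFFECT_THRESHOLD
) -> Optional[float]:
    """Highest tested concentration with mean effect <= threshold vs control.

    Concentrations are scanned in increasing order and the scan stops at the
    first exceedance, so a noisy non-monotone recovery at high doses cannot
    rescue the NOEC.  Returns None when even the lowest dose shows an effect.
    """
    control = table.loc[table["concentration"] == 0.0, "response"].mean()
    noec = None
    for conc, mean in (
        table[table["concentration"] > 0].groupby("concentration")["response"].mean().items()
    ):
        effect = 1.0 - mean / control
        if effect > effect_threshold:
            break
        noec = float(conc)
    return noec


# --- reference case -----------------------------------------------------

_INGREDIENT2_HAZARDS = (
    HazardEntry(hazard_class="acute_toxicity_oral", category="4", h_code="H302"),
    HazardEntry(hazard_class="eye_irritation", category="2", h_code="H319"),
    HazardEntry(hazard_class="skin_sensitisation", category="1", h_code="H317"),
    HazardEntry(hazard_class="aquatic_chronic", category="2", h_code="H411"),
)

#: True EC50s (mg/L) behind the simulated tier-1 endpoints.
_AF1_TRUE_EC50 = {
    Assay.OECD202_DAPHNIA: 5.0,
    Assay.OECD201_ALGAE: 0.5,  # drives the Acute 1 call
    Assay.ISO11348_ALIIVIBRIO: 20.0,
}
_AF2_TRUE_EC50 = {
    Assay.OECD202_DAPHNIA: 8.0,
    Assay.OECD201_ALGAE: 12.0,
    Assay.ISO11348_ALIIVIBRIO: 30.0,
}
#: Chronic reproduction curve for AF2: effects stay under the 10 % threshold
#: up to 0.05 mg/L and exceed it at 0.1 mg/L, giving a NOEC in (0.01, 0.1].
_AF2_CHRONIC = dict(ec50=0.18, slope=2.0, noise_sd=0.01)
_AF2_CHRONIC_CONCS = (0.01, 0.05, 0.1, 0.5, 1.0)


def _ing1(fraction) -> Ingredient:
    return Ingredient(
        id="ingredient_1",
        name="nano consolidant binder",
        mass_fraction=fraction,
        is_nanoform=True,
    )


def _ing2(fraction) -> Ingredient:
    return Ingredient(
        id="ingredient_2",
        name="volatile co-solvent",
        mass_fraction=fraction,
        hazards=_INGREDIENT2_HAZARDS,
        ate={"oral": 500.0},
        is_volatile=True,
    )


def _water(fraction) -> Ingredient:
    return Ingredient(id="water", name="water", mass_fraction=fraction)


@dataclass(frozen=True)
class CaseStudyBundle:
    """IF/AF1/AF2 formulations plus simulated bioassay endpoints and scorecards."""

    seed: int
    formulations: dict[str, Formulation]
    bioassays: dict[str, list[BioassayResult]]
    dose_response: dict[str, pd.DataFrame]
    scorecards: dict[str, list[dict]]


def _acute_endpoints(
    true_ec50s: dict[Assay, float], seed: int
) -> tuple[list[BioassayResult], dict[str, pd.DataFrame]]:
    results, tables = [], {}
    for k, (assay, ec50) in enumerate(sorted(true_ec50s.items(), key=lambda kv: kv[0].value)):
        curve = DoseResponseCurve(ec50=ec50, slope=2.0, noise_sd=0.02, seed=seed + k)
        table, fit = simulate_bioassay(curve)
        if fit.status != "converged":  # pragma: no cover - generous designs converge
            raise RuntimeError(f"simulated assay {assay.value} failed to converge")
        results.append(
            BioassayResult(
                assay=assay, endpoint_type=EndpointType.EC50, value=fit.ec50, units="mg/L"
            )
        )
        tables[assay.value] = table
    return results, tables


def make_case_study_fixtures(seed: int = 0) -> CaseStudyBundle:
    """Generate the reference consolidant case, reproducibly from ``seed``.

    IF carries ingredient 2 at a 30-40 % w/w range; AF1 reduces it to 0.70 %,
    AF2 to 0.01 % while adding a non-hazardous ingredient 3.  Tier-1 acute
    endpoints are simulated so AF1 shows an algal EC50 below 1 mg/L and AF2
    stays above 1 mg/L for all species; AF2's chronic reproduction test yields
    a NOEC in (0.01, 0.1] mg/L.
    """
    formulations = {
        "IF": Formulation(
            id="IF",
            label="initial formulation",
            ingredients=(_ing1((5.0, 10.0)), _ing2((30.0, 40.0)), _water(57.0)),
        ),
        "AF1": Formulation(
            id="AF1",
            label="adjusted formulation 1",
            ingredients=(_ing1((5.0, 10.0)), _ing2(0.70), _water(91.0)),
        ),
        "AF2": Formulation(
            id="AF2",
            label="adjusted formulation 2",
            ingredients=(
                _ing1(0.70),
                _ing2(0.01),
                Ingredient(
                    id="ingredient_3",
                    name="non-hazardous dispersant",
                    mass_fraction=0.20,
                ),
                _water(99.09),
            ),
        ),
    }

    af1_results, af1_tables = _acute_endpoints(_AF1_TRUE_EC50, seed=seed * 101 + 11)
    af2_results, af2_tables = _acute_endpoints(_AF2_TRUE_EC50, seed=seed * 101 + 47)

    chronic_curve = DoseResponseCurve(
        concentrations=_AF2_CHRONIC_CONCS, replicates=4, seed=seed * 101 + 83, **_AF2_CHRONIC
    )
    chronic_table = _simulate_table(chronic_curve)
    noec = estimate_noec(chronic_table)
    if noec is None:  # pragma: no cover - margin >5 sd at the design noise
        raise RuntimeError("chronic simulation produced no NOEC")
    af2_results.append(
        BioassayResult(
            assay=Assay.OECD211_DAPHNIA_REPRO,
            endpoint_type=EndpointType.NOEC,
            value=noec,
            units="mg/L",
        )
    )
    # tier-3 screens for completeness (AF2 never reaches them: tier 2 decides)
    af2_results.append(
        BioassayResult(
            assay=Assay.UMU_ISO13829,
            endpoint_type=EndpointType.INDUCTION_RATIO,
            value=1.1,
            units="",
        )
    )

    dose_response = {f"AF1/{k}": v for k, v in af1_tables.items()}
    dose_response.update({f"AF2/{k}": v for k, v in af2_tables.items()})
    dose_response["AF2/OECD211_daphnia_repro"] = chronic_table

    scorecards = {
        # AF2: environmental pillar auto-populated from the safety band;
        # technological excellent; economic and social slightly lower.
        "AF2": [
            {"pillar": "technological", "indicator": "efficiency", "score": 5},
            {"pillar": "technological", "indicator": "compatibility", "score": 5},
            {"pillar": "economic", "indicator": "market_size", "score": 5},
            {"pillar": "economic", "indicator": "upscaling_investment", "score": 4},
            {"pillar": "social_ethical_legal", "indicator": "retreatability", "score": 5},
            {"pillar": "social_ethical_legal", "indicator": "regulatory_barriers", "score": 4},
        ],
        # Illustrative conventional product: more hazardous, worse performance.
        "CP": [
            {"pillar": "environmental", "indicator": "safety_band", "score": 2},
            {"pillar": "technological", "indicator": "efficiency", "score": 3},
            {"pillar": "technological", "indicator": "compatibility", "score": 3},
            {"pillar": "economic", "indicator": "market_size", "score": 5},
            {"pillar": "economic", "indicator": "upscaling_investment", "score": 4},
            {"pillar": "social_ethical_legal", "indicator": "retreatability", "score": 3},
            {"pillar": "social_ethical_legal", "indicator": "regulatory_barriers", "score": 4},
        ],
    }

    return CaseStudyBundle(
        seed=seed,
        formulations=formulations,
        bioassays={"AF1": af1_results, "AF2": af2_results},
        dose_response=dose_response,
        scorecards=scorecards,
    )


def write_case_study(bundle: CaseStudyBundle, out_dir) -> list[Path]:
    """Write the bundle as formulation YAML + bioassay/dose-response CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fid, f in bundle.formulations.items():
        written.append(write_formulation(f, out / f"{fid}.yaml"))
    for fid, results in bundle.bioassays.items():
        written.append(write_bioassays(results, out / f"{fid}_bioassays.csv"))
    for key, table in bundle.dose_response.items():
        path = out / f"{key.replace('/', '_')}_doseresponse.csv"
        header = f"# seed={bundle.seed}\n"
        path.write_text(header + table.to_csv(index=False))
        written.append(path)
    import yaml as _yaml

    for pid, card in bundle.scorecards.items():
        path = out / f"{pid}_scorecard.yaml"
        path.write_text(_yaml.safe_dump({"product": pid, "indicators": card}, sort_keys=False))
        written.append(path)
    return written


# --- random formulations for property-based testing ----------------------

_RANDOM_HAZARD_POOL = (
    HazardEntry(hazard_class="skin_irritation", category="2", h_code="H315"),
    HazardEntry(hazard_class="eye_irritation", category="2", h_code="H319"),
    HazardEntry(hazard_class="skin_sensitisation", category="1", h_code="H317"),
    HazardEntry(hazard_class="acute_toxicity_oral", category="4", h_code="H302"),
    HazardEntry(hazard_class="acute_toxicity_oral", category="3", h_code="H301"),
    HazardEntry(hazard_class="aquatic_acute", category="1", h_code="H400"),
    HazardEntry(hazard_class="aquatic_chronic", category="1", h_code="H410"),
    HazardEntry(hazard_class="aquatic_chronic", category="2", h_code="H411"),
    HazardEntry(hazard_class="aquatic_chronic", category="3", h_code="H412"),
)


def random_formulation(
    n_ingredients: int, hazard_density: float, seed: int
) -> Formulation:
    """A valid random formulation (fractions summing to 100 % w/w).

    Each ingredient is hazardous with probability ``hazard_density`` and then
    draws 1-2 hazard entries from a pool covering all three rule methods.
    """
    if n_ingredients < 1:
        raise ValueError("need at least one ingredient")
    if not 0.0 <= hazard_density <= 1.0:
        raise ValueError("hazard_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet(np.ones(n_ingredients)) * 100.0
    ingredients = []
    for k, frac in enumerate(fractions):
        hazards: tuple[HazardEntry, ...] = ()
        if rng.random() < hazard_density:
            n_hz = int(rng.integers(1, 3))
            idx = rng.choice(len(_RANDOM_HAZARD_POOL), size=n_hz, replace=False)
            hazards = tuple(_RANDOM_HAZARD_POOL[i] for i in sorted(idx))
        ingredients.append(
            Ingredient(
                id=f"ing_{k}",
                name=f"random ingredient {k}",
                mass_fraction=round(float(frac), 6),
                hazards=hazards,
                m_factor_acute=float(rng.choice([1.0, 1.0, 10.0])) if hazards else 1.0,
                m_factor_chronic=float(rng.choice([1.0, 1.0, 10.0])) if hazards else 1.0,
                is_volatile=bool(rng.random() < 0.3),
            )
        )
    return Formulation(id=f"random_{seed}", label="random", ingredients=tuple(ingredients))
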