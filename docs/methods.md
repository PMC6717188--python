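# Methods

## Scope and model

`sbdkit` operationalises a stepwise safe-by-design assessment of liquid
formulations: calculation-based mixture hazard screening, reformulation
guidance, a tiered experimental strategy for aquatic hazard, semi-quantitative
safety banding, and MCDA sustainability ranking. It is a screening-level
decision aid, not a regulatory compliance tool: the shipped rule registry
covers only the hazard classes needed for the reference consolidant case
(acute oral toxicity 1–4, skin/eye irritation 2, skin sensitisation 1/1A/1B,
aquatic acute 1 and chronic 1–4), and the registry file format is extensible
for other classes.

## Screening classification

Every rule uses the same boundary convention: **"≥" triggers**. An ingredient
at exactly the generic cut-off is taken into account; a mixture at exactly
the GCL (or a summation sum exactly at its threshold) is classified.
Adjustment bounds are correspondingly *open*: a hazard disappears strictly
below its bound.

- *Worst case on ranges.* SDS compositions often come as intervals; the
  engine classifies at the interval upper bound and reports adjustment
  bounds against it. The nominal (midpoint) composition must sum to at most
  100 % plus a 0.5-point tolerance (configurable per formulation) to absorb
  rounding in SDS data.
- *Additivity.* `100/ATE_mix = Σ c_i/ATE_i` over components at ≥ 1 %. A
  component declaring only a category uses the registry's converted point
  estimate (cat 1 → 0.5, 2 → 5, 3 → 100, 4 → 500 mg/kg bw), the standard
  practice when the SDS states no numeric ATE. The mixture is classified in
  the narrowest band containing `ATE_mix` (edges 5/50/300/2000 mg/kg).
- *Summation.* The shipped aquatic-chronic rows weight every contributing
  category at its plain M-factored concentration — deliberately **without**
  the 10×/100× severity-escalation factors of the full regulation. Under
  this convention a mixture sheds all aquatic-chronic classification as soon
  as the weighted sum of classified components drops below 25 % w/w, which is
  exactly the screening guidance the adjustment engine is meant to emit
  ("reduce below 25 % to avoid the aquatic hazard"). The registry format
  carries per-row multipliers, so the escalated weights can be supplied as an
  override where full-regulation behaviour is wanted; the bundled defaults
  favour the simpler, self-consistent screening story.
- *Unknown-hazard ingredients.* An ingredient without an SDS cannot be
  classified; its fraction is booked as `unknown_fraction`. At ≥ 10 % a
  warning is attached (no hazard is invented for it); a formulation with no
  classifiable ingredient at all is flagged `not_classifiable`.

### Adjustment bounds

For each (ingredient, hazard class) the removal bound is solved analytically:
`max(cutoff, GCL − others)` for threshold rules,
`max(cutoff, ATE_i·(100/2000 − Σ_{j≠i} c_j/ATE_j))` for additivity, and
`max(cutoff, min over rows (threshold − others_row)/w_row)` for summation.
If the remaining ingredients trigger the rule alone, no bound exists and the
hazard is reported as unremovable via that ingredient; if other ingredients
contribute at all, the suggestion carries a `joint` flag (the bound holds
with the others fixed). Every bound is verified by re-classification at
`bound − 1e-9`; the test suite additionally cross-checks all fixture bounds
against a brute-force 0.01 %-grid scan. Bounds per ingredient are reported
descending, with cumulative removal sets, so each smaller bound removes a
superset of hazards.

With the reference ingredient 2 (acute oral cat 4 with the converted ATE of
500 mg/kg, eye irritation 2, skin sensitisation 1, aquatic chronic 2, M = 1)
the bounds come out 25 % (aquatic chronic — and, coincidentally at this ATE,
acute oral, since `ATE_mix = 2000` exactly at 25 %), 10 % (eye irritation)
and 1 % (skin sensitisation, leaving no hazards).

## Tiered testing strategy

Tier 1 requires all three acute assays; tier 2 requires the chronic NOEC.
Missing data yields an explicit `incomplete` outcome — never a silent pass.
Duplicate endpoints for one assay are an error unless the `min` aggregation
policy is enabled. NOEC boundary semantics are Chronic 1 ≤ 0.01 <
Chronic 2 ≤ 0.1 < Chronic 3 ≤ 1 mg/L (inclusive upper edges, chosen so the
three bands partition the axis without overlap). The genotoxicity screens
are called positive at an induction ratio ≥ 1.5 (configurable), the common
umu-test convention; a tier-3 alert is carried as a warning on the merged
classification and deliberately **not** counted as an ENV hazard, since the
banding scheme defines its hazard axis by classified H/ENV hazards only.
All concentrations are mg/L; the CSV reader normalises µg/L and g/L.

## Exposure and safety banding

Stated as verbal ranges, the low band ends at 10 % while the medium band
starts at 11 %, leaving (10, 11) % undefined; the implementation closes the
gap at 10 (low = [1, 10], medium = (10, 50]) so the bands are contiguous and
every edge (1, 10, 50) is preserved. Applying all recommended RMMs forces
the negligible band regardless of concentration.

The 5×4 matrix's hazard axis uses count bands {0}, {1–2}, {3–4}, {5–6},
{≥ 7}, inferred from the two fixed corners ("up to two hazards" excellent at
up to 10 % volatiles; "more than six" bad above 50 %). Only those corners are
externally fixed; the interior default

| hazards \ exposure | negligible | low | medium | high |
|---|---|---|---|---|
| 0 | excellent | excellent | good | good |
| 1–2 | excellent | excellent | good | moderate |
| 3–4 | good | good | moderate | poor |
| 5–6 | moderate | moderate | poor | poor |
| ≥ 7 | moderate | poor | poor | bad |

interpolates monotonically and is overridable; overrides are validated for
shape and monotonicity (safety must never improve with more hazards or worse
exposure). The hazard count tallies distinct hazard *classes* — a category
upgrade of an already-counted class does not double-count. `RCR = PEC/PNEC`
uses `PNEC = min(endpoints)/AF`, AF = 1000 for acute-only data and 10 with a
chronic NOEC (both overridable); PEC derivation (environmental fate) is out
of scope — the ratio is computed for a user-supplied PEC, reflecting that a
bound consolidant's post-application release is assumed negligible.

## MCDA

Weighted arithmetic means at both levels (indicators → pillar, pillars →
overall) — the simplest aggregation consistent with a five-class satisfaction
scale; weights are normalised within each level, so scaling all weights by a
positive constant changes nothing. The environmental pillar may be
auto-populated from the safety band via the excellent→5 … bad→1 bijection;
economic/social/technological indicators are user-supplied judgements
(market size, regulatory barriers, compatibility, …) — no attempt is made to
compute them from raw data. Ties on the overall score break by comparing
pillar scores environmental-first, then by product id; the rule is declared
on every result.

## Synthetic data

The generator emulates the study conditions of the reference case:

- ingredient 2 at 30–40 % (IF), 0.70 % (AF1) and 0.01 % (AF2), AF2 adding a
  non-hazardous ingredient 3 and being > 99 % water + nano-binder;
- tier-1 endpoints simulated from two-parameter log-logistic curves
  (`response = 1/(1 + (c/EC50)^slope)`, Gaussian replicate noise, sd 0.02,
  7 concentrations × 3 replicates spanning the true EC50 tenfold each way),
  re-estimated by least squares; true EC50s 5/0.5/20 mg/L for AF1 (algae
  drive the Acute 1 call) and 8/12/30 mg/L for AF2;
- the chronic test for AF2 (true EC50 0.18 mg/L, slope 2, sd 0.01, doses
  0.01–1 mg/L × 4 replicates) yields its NOEC as the highest dose whose mean
  response stays within 10 % of control, scanning upward and stopping at the
  first exceedance — a pragmatic stand-in for the hypothesis-testing NOEC of
  the reproduction guideline, documented as a simplification. By design the
  NOEC lands at 0.05 mg/L (Chronic 2) with a > 5 σ margin at the chosen
  noise, so the qualitative trajectory is stable across seeds.

All randomness flows from one integer seed (file outputs record it in a
header). The generator does not emulate real-data features such as
nanoparticle transformation/fate, inter-laboratory variance, solvent
controls or hormesis; passing tests therefore demonstrate the correctness of
the decision logic under clean monotone dose-response data, not field
performance of the assays. `random_formulation` draws Dirichlet compositions
(summing to 100 %) with hazard profiles sampled at a chosen density across
all three rule methods, for property-based testing of monotonicity and
dilution invariants.

## Numerical choices

- Bound verification offset 1e-9 %; grid cross-checks use 0.01 % steps.
- EC50 fitting: `scipy.optimize.curve_fit` on all replicate points, p0 at the
  geometric-mean dose with slope 1, bounds keeping EC50 within two decades of
  the tested range; a fit is declared non-converged when the mean response
  does not descend by at least 0.1, never crosses 0.7/0.3, or the optimiser
  fails. The 95 % CI is the Wald interval from the covariance.
- Determinism: classification output is independent of ingredient order
  (rules are evaluated in a fixed class/category order); reports serialise
  with sorted keys; the pipeline's provenance hash covers the full config.

## Problem sizes

The test suite and the acceptance script run at desk scale: concentration
grids of ≤ 4 101 points, 1 000 random formulations for the invariants, 100
simulation seeds per noise level for EC50 recovery — a few seconds each on
one core, chosen because the decision rules are step functions whose
behaviour is fully determined by their (few) breakpoints.

## Known limitations

- The registry is a curated subset; classes outside it raise an explicit
  error rather than being silently skipped.
- Cross-class contributions (e.g. corrosive components counting toward
  irritation rows at reduced weight) are not modelled.
- The simplified summation weights understate mixture severity relative to
  the full escalated cascade for mixtures dominated by higher-severity
  aquatic components (see above for the override path).
- Gate policy defaults (Acute 1 → discard, Chronic 1 → adjust, Chronic 2/3 →
  proceed with flag) are a documented default for the stage-gate flag, fully
  configurable, not a normative claim.
- Exposure banding is a volatile-fraction proxy; no occupational exposure
  modelling or measurement is attempted.
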