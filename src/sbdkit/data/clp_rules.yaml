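# Classification-rule registry: the subset of CLP-style mixture rules needed
# for screening self-classification of conservation formulations.
#
# Boundary convention throughout: ">=" triggers — an ingredient at exactly the
# generic cut-off is taken into account, a mixture at exactly the GCL (or a
# summation sum at exactly the threshold) is classified.
#
# The aquatic-chronic summation rows deliberately weight every contributing
# category at its plain (M-factored) concentration, without the 10x/100x
# severity escalation of the full regulation: under this convention a mixture
# drops all aquatic-chronic classification as soon as the M-weighted sum of
# classified components falls below 25 % w/w, which is the screening guidance
# the package implements.  Override files may supply escalated multipliers.
schema_version: 1
registry_version: "sbdkit-clp-1"
rules:
  - hazard_class: skin_irritation
    category: "2"
    h_code: H315
    method: threshold
    generic_cutoff: 1.0
    gcl: 10.0

  - hazard_class: eye_irritation
    category: "2"
    h_code: H319
    method: threshold
    generic_cutoff: 1.0
    gcl: 10.0

  - hazard_class: skin_sensitisation
    category: "1"
    h_code: H317
    method: threshold
    generic_cutoff: 0.1
    gcl: 1.0

  - hazard_class: skin_sensitisation
    category: "1A"
    h_code: H317
    method: threshold
    generic_cutoff: 0.01
    gcl: 0.1

  - hazard_class: skin_sensitisation
    category: "1B"
    h_code: H317
    method: threshold
    generic_cutoff: 0.1
    gcl: 1.0

  # Acute oral toxicity: reciprocal additivity over components present at
  # >= 1 %; the mixture ATE is banded into categories 1-4.  conversion_values
  # supply a point ATE for components that declare only a category.
  - hazard_class: acute_toxicity_oral
    category: "*"
    method: additivity
    generic_cutoff: 1.0
    parameters:
      route: oral
      bands:
        - {category: "1", max_ate: 5.0, h_code: H300}
        - {category: "2", max_ate: 50.0, h_code: H300}
        - {category: "3", max_ate: 300.0, h_code: H301}
        - {category: "4", max_ate: 2000.0, h_code: H302}
      conversion_values: {"1": 0.5, "2": 5.0, "3": 100.0, "4": 500.0}

  - hazard_class: aquatic_acute
    category: "1"
    h_code: H400
    method: summation
    generic_cutoff: 0.1
    parameters:
      threshold: 25.0
      components:
        - {hazard_class: aquatic_acute, category: "1", multiplier: 1.0, m_factor: acute}

  - hazard_class: aquatic_chronic
    category: "1"
    h_code: H410
    method: summation
    generic_cutoff: 0.1
    parameters:
      threshold: 25.0
      components:
        - {hazard_class: aquatic_chronic, category: "1", multiplier: 1.0, m_factor: chronic}

  - hazard_class: aquatic_chronic
    category: "2"
    h_code: H411
    method: summation
    generic_cutoff: 1.0
    parameters:
      threshold: 25.0
      components:
        - {hazard_class: aquatic_chronic, category: "1", multiplier: 1.0, m_factor: chronic}
        - {hazard_class: aquatic_chronic, category: "2", multiplier: 1.0, m_factor: none}

  - hazard_class: aquatic_chronic
    category: "3"
    h_code: H412
    method: summation
    generic_cutoff: 1.0
    parameters:
      threshold: 25.0
      components:
        - {hazard_class: aquatic_chronic, category: "1", multiplier: 1.0, m_factor: chronic}
        - {hazard_class: aquatic_chronic, category: "2", multiplier: 1.0, m_factor: none}
        - {hazard_class: aquatic_chronic, category: "3", multiplier: 1.0, m_factor: none}

  - hazard_class: aquatic_chronic
    category: "4"
    h_code: H413
    method: summation
    generic_cutoff: 1.0
    parameters:
      threshold: 25.0
      components:
        - {hazard_class: aquatic_chronic, category: "1", multiplier: 1.0, m_factor: none}
        - {hazard_class: aquatic_chronic, category: "2", multiplier: 1.0, m_factor: none}
        - {hazard_class: aquatic_chronic, category: "3", multiplier: 1.0, m_factor: none}
        - {hazard_class: aquatic_chronic, category: "4", multiplier: 1.0, m_factor: none}
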