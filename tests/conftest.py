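import pytest

from sbdkit import make_case_study_fixtures, load_rule_registry
from sbdkit.core import Formulation, HazardEntry, Ingredient


@pytest.fixture(scope="session")
def registry():
    return load_rule_registry()


@pytest.fixture(scope="session")
def bundle():
    return make_case_study_fixtures(seed=1)


@pytest.fixture()
def skin_irritant():
    """One skin-irritant (cat 2) ingredient factory at a given % w/w."""

    def make(fraction, ing_id="irritant"):
        return Ingredient(
            id=ing_id,
            name="skin irritant",
            mass_fraction=fraction,
            hazards=(HazardEntry(hazard_class="skin_irritation", category="2", h_code="H315"),),
        )

    return make


@pytest.fixture()
def water_mix(skin_irritant):
    """Two-component mixture: one skin irritant at `fraction` %, remainder water."""

    def make(fraction):
        return Formulation(
            id="probe",
            ingredients=(
                skin_irritant(fraction),
                Ingredient(id="water", name="water", mass_fraction=100.0 - fraction),
            ),
        )

    return make
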