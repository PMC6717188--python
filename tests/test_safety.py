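"""Exposure banding, control-banding matrix and PEC/PNEC risk ratio."""

import itertools

import numpy as np
import pytest

from sbdkit.core import Assay, BioassayResult, ConfigurationError, SbdError
from sbdkit.its import merge_with_screening, run_its
from sbdkit.safety import (
    DEFAULT_MATRIX,
    ExposureBand,
    SafetyBand,
    assess_safety,
    band_exposure,
    band_from_fraction,
    hazard_class_index,
    render_matrix,
    risk_ratio,
)
from sbdkit.screening import MixtureClassification, classify_mixture

_RANK = {b: i for i, b in enumerate(SafetyBand)}


def classification_with_count(n):
    """A synthetic merged classification carrying n distinct hazard classes."""
    from sbdkit.core import HazardEntry, Scope
    from sbdkit.screening import AssignedHazard, Driver

    classes = [
        "skin_irritation", "eye_irritation", "skin_sensitisation", "acute_toxicity_oral",
        "aquatic_chronic", "aquatic_acute", "resp_irritation", "stot_se", "carcinogenicity",
    ]
    assigned = tuple(
        AssignedHazard(
            entry=HazardEntry(hazard_class=classes[k], category="2"),
            driver=Driver(method="threshold"),
        )
        for k in range(n)
    )
    n_h = sum(1 for a in assigned if a.entry.scope is Scope.H)
    return MixtureClassification(
        formulation_id="synthetic",
        assigned=assigned,
        count_H=n_h,
        count_ENV=len(assigned) - n_h,
    )


class TestExposureBanding:
    @pytest.mark.parametrize(
        "fraction,expected",
        [
            (0.0, "negligible"),
            (0.999, "negligible"),
            (1.0, "low"),
            (10.0, "low"),
            (10.001, "medium"),
            (30.0, "medium"),
            (50.0, "medium"),
            (50.001, "high"),
            (70.0, "high"),
        ],
    )
    def test_band_edges(self, fraction, expected):
        assert band_from_fraction(fraction, rmms_applied=False).value == expected

    def test_rmms_override_forces_negligible(self):
        assert band_from_fraction(70.0, rmms_applied=True) is ExposureBand.NEGLIGIBLE

    def test_step_function_has_exactly_three_jumps(self):
        grid = np.arange(0.0, 100.0001, 0.05)
        bands = [band_from_fraction(x, False) for x in grid]
        changes = [g for g, a, b in zip(grid[1:], bands, bands[1:]) if a != b]
        assert len(changes) == 3
        assert np.allclose(changes, [1.0, 10.05, 50.05], atol=0.051)

    def test_af2_negligible_with_and_without_rmms(self, bundle):
        f = bundle.formulations["AF2"]
        assert band_exposure(f, rmms_applied=False).band is ExposureBand.NEGLIGIBLE
        assert band_exposure(f, rmms_applied=True).band is ExposureBand.NEGLIGIBLE

    def test_only_hazardous_volatiles_count(self, bundle):
        # IF's volatile ingredient 2 sits at a 30-40% range: medium without RMMs
        e = band_exposure(bundle.formulations["IF"], rmms_applied=False)
        assert e.hazardous_volatile_fraction == pytest.approx(40.0)
        assert e.band is ExposureBand.MEDIUM


class TestSafetyMatrix:
    def test_af2_lands_excellent(self, registry, bundle):
        screening = classify_mixture(bundle.formulations["AF2"], registry)
        merged = merge_with_screening(screening, run_its(bundle.bioassays["AF2"]))
        e = band_exposure(bundle.formulations["AF2"], rmms_applied=False)
        a = assess_safety(merged, e)
        assert a.hazard_count == 1 and a.band is SafetyBand.EXCELLENT

    @pytest.mark.parametrize(
        "count,fraction,expected",
        [
            (0, 0.0, "excellent"),   # best corner
            (2, 10.0, "excellent"),  # top cell group boundary
            (7, 70.0, "bad"),        # worst corner
            (9, 70.0, "bad"),
        ],
    )
    def test_matrix_corners(self, count, fraction, expected):
        e = band_from_fraction(fraction, False)
        from sbdkit.safety import ExposureAssessment

        exposure = ExposureAssessment(
            hazardous_volatile_fraction=fraction, rmms_applied=False, band=e
        )
        a = assess_safety(classification_with_count(count), exposure)
        assert a.band.value == expected

    def test_hazard_count_bands(self):
        assert [hazard_class_index(n) for n in (0, 1, 2, 3, 4, 5, 6, 7, 12)] == [
            1, 2, 2, 3, 3, 4, 4, 5, 5,
        ]

    def test_full_matrix_monotone(self):
        """Safety never improves when hazards increase or exposure worsens."""
        from sbdkit.safety import ExposureAssessment

        fractions = [0.0, 5.0, 30.0, 70.0]
        counts = [0, 1, 3, 5, 7]
        for (i, n), (j, x) in itertools.product(enumerate(counts), enumerate(fractions)):
            exposure = ExposureAssessment(
                hazardous_volatile_fraction=x, rmms_applied=False,
                band=band_from_fraction(x, False),
            )
            here = assess_safety(classification_with_count(n), exposure)
            if i + 1 < len(counts):
                worse = assess_safety(classification_with_count(counts[i + 1]), exposure)
                assert _RANK[worse.band] >= _RANK[here.band]
            if j + 1 < len(fractions):
                exposure2 = ExposureAssessment(
                    hazardous_volatile_fraction=fractions[j + 1], rmms_applied=False,
                    band=band_from_fraction(fractions[j + 1], False),
                )
                worse = assess_safety(classification_with_count(n), exposure2)
                assert _RANK[worse.band] >= _RANK[here.band]

    def test_category_upgrade_does_not_double_count(self, registry, bundle):
        screening = classify_mixture(bundle.formulations["IF"], registry)
        merged = merge_with_screening(screening, run_its(bundle.bioassays["AF1"]))
        # experimental Acute1 adds aquatic_acute; calculated aquatic_chronic stays
        assert merged.hazard_count == screening.hazard_count + 1

    def test_non_monotone_override_rejected(self):
        bad = [list(row) for row in DEFAULT_MATRIX]
        bad[4][3] = "excellent"
        from sbdkit.safety import ExposureAssessment

        exposure = ExposureAssessment(
            hazardous_volatile_fraction=0.0, rmms_applied=False, band=ExposureBand.NEGLIGIBLE
        )
        with pytest.raises(ConfigurationError, match="improves"):
            assess_safety(classification_with_count(0), exposure, matrix=bad)

    def test_wrong_shape_override_rejected(self):
        from sbdkit.safety import ExposureAssessment

        exposure = ExposureAssessment(
            hazardous_volatile_fraction=0.0, rmms_applied=False, band=ExposureBand.NEGLIGIBLE
        )
        with pytest.raises(ConfigurationError, match="5 rows"):
            assess_safety(
                classification_with_count(0), exposure, matrix=[["excellent"] * 4] * 3
            )

    def test_render_marks_the_cell(self):
        from sbdkit.safety import ExposureAssessment

        exposure = ExposureAssessment(
            hazardous_volatile_fraction=0.0, rmms_applied=False, band=ExposureBand.NEGLIGIBLE
        )
        a = assess_safety(classification_with_count(1), exposure)
        assert "[excellent]" in render_matrix(a)


class TestRiskRatio:
    def test_chronic_assessment_factor_10(self):
        endpoints = [
            BioassayResult(assay=Assay.OECD211_DAPHNIA_REPRO, endpoint_type="NOEC", value=0.05)
        ]
        r = risk_ratio(0.0005, endpoints)
        assert r.pnec == pytest.approx(0.005)
        assert r.rcr == pytest.approx(0.1)
        assert r.safe and not r.boundary

    def test_acute_only_assessment_factor_1000(self):
        endpoints = [
            BioassayResult(assay=Assay.OECD202_DAPHNIA, endpoint_type="EC50", value=2.0)
        ]
        r = risk_ratio(0.002, endpoints)
        assert r.assessment_factor == 1000.0
        assert r.pnec == pytest.approx(0.002)
        assert r.rcr == pytest.approx(1.0)
        assert r.boundary and not r.safe

    def test_most_sensitive_endpoint_drives_pnec(self):
        endpoints = [
            BioassayResult(assay=Assay.OECD202_DAPHNIA, endpoint_type="EC50", value=2.0),
            BioassayResult(assay=Assay.OECD201_ALGAE, endpoint_type="EC50", value=0.5),
        ]
        assert risk_ratio(0.001, endpoints).pnec == pytest.approx(0.0005)

    def test_rcr_scales_linearly_in_pec_and_inversely_in_pnec(self):
        endpoints = [
            BioassayResult(assay=Assay.OECD211_DAPHNIA_REPRO, endpoint_type="NOEC", value=0.05)
        ]
        r1 = risk_ratio(0.001, endpoints)
        r2 = risk_ratio(0.003, endpoints)
        assert r2.rcr == pytest.approx(3 * r1.rcr)
        r3 = risk_ratio(0.001, endpoints, assessment_factor=100.0)
        assert r3.rcr == pytest.approx(10 * r1.rcr)

    def test_errors(self):
        endpoints = [
            BioassayResult(assay=Assay.OECD202_DAPHNIA, endpoint_type="EC50", value=2.0)
        ]
        with pytest.raises(SbdError, match="positive"):
            risk_ratio(0.0, endpoints)
        with pytest.raises(SbdError, match="endpoint"):
            risk_ratio(0.001, [])
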