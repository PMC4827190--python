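"""Evidence-to-code rubrics: band examples, totality, monotonicity, pilot."""

import numpy as np
import pytest

from htaprio import fixtures
from htaprio.errors import InvalidInputError
from htaprio.rubrics import (
    EvidenceProfile,
    build_decision_matrix,
    code_alternatives_availability,
    code_budget_impact,
    code_cost_effectiveness,
    code_effectiveness,
    code_evidence_quality,
    code_financial_protection,
    code_population_size,
    code_profile,
    code_safety,
    code_vulnerable_share,
    default_rubrics,
)


class TestEffectiveness:
    @pytest.mark.parametrize(
        "label, code",
        [
            ("perfect treatment", 5),
            ("lifetime increasing and major improvement of quality of life", 4),
            ("lifetime increasing and low improvement of quality of life", 3),
            ("major improvement of quality of life", 2),
            ("low improvement of quality of life", 1),
        ],
    )
    def test_treatment_labels(self, label, code):
        assert code_effectiveness("treatment", label) == code

    @pytest.mark.parametrize(
        "accuracy, treatable, code",
        [(85, True, 5), (70, True, 4), (85, False, 3), (70, False, 2),
         (60, True, 4), (50, True, 1), (50, False, 1)],
    )
    def test_screening_accuracy_bands(self, accuracy, treatable, code):
        got = code_effectiveness("screening", {"accuracy": accuracy, "treatable": treatable})
        assert got == code

    @pytest.mark.parametrize(
        "pct, code", [(95, 5), (85, 4), (75, 3), (65, 2), (60, 1), (50, 1), (90, 4)]
    )
    def test_prevention_bands(self, pct, code):
        assert code_effectiveness("prevention", pct) == code

    def test_class_descriptor_mismatch(self):
        with pytest.raises(InvalidInputError):
            code_effectiveness("treatment", 85.0)
        with pytest.raises(InvalidInputError):
            code_effectiveness("screening", "perfect treatment")
        with pytest.raises(InvalidInputError):
            code_effectiveness("banana", "perfect treatment")


class TestSafety:
    @pytest.mark.parametrize(
        "incidence, code",
        [(0.5, 5), (1.0, 4), (9.9, 4), (10.0, 3), (39.0, 3), (40.0, 2),
         (50.0, 2), (51.0, 1), (100.0, 1)],
    )
    def test_numeric_bands(self, incidence, code):
        assert code_safety(incidence=incidence) == code

    @pytest.mark.parametrize(
        "level, code",
        [
            ("completely safe (lack of side effects)", 5),
            ("relatively safe (mild and slight side effects)", 4),
            ("proper safety", 3),
            ("poor safety", 2),
            ("unsafe (major side effects)", 1),
        ],
    )
    def test_qualitative_levels(self, level, code):
        assert code_safety(level=level) == code

    def test_numeric_takes_precedence_over_level(self):
        assert code_safety(incidence=0.2, level="unsafe") == 5

    def test_no_unspecified_band(self):
        with pytest.raises(InvalidInputError):
            code_safety()

    def test_unknown_level_rejected(self):
        with pytest.raises(InvalidInputError):
            code_safety(level="fairly ok")


class TestNumericRubrics:
    @pytest.mark.parametrize(
        "n, code",
        [(180_000, 4), (10_000, 1), (500_001, 5), (500_000, 4), (100_001, 4),
         (100_000, 3), (50_001, 3), (10_001, 2), (0, 1)],
    )
    def test_population_bands(self, n, code):
        assert code_population_size(n) == code

    def test_negative_population_rejected(self):
        with pytest.raises(InvalidInputError):
            code_population_size(-5)

    @pytest.mark.parametrize(
        "share, code",
        [(None, 1), (8, 2), (10, 2), (10.5, 3), (11, 3), (25, 3), (26, 4),
         (40, 4), (50, 4), (51, 5), (100, 5)],
    )
    def test_vulnerable_bands_with_gap_filled(self, share, code):
        assert code_vulnerable_share(share) == code

    def test_vulnerable_share_out_of_range(self):
        with pytest.raises(InvalidInputError):
            code_vulnerable_share(104)

    @pytest.mark.parametrize(
        "icer, gdp, code",
        [(6255, 53_000, 5), (16_000, 53_000, 5), (None, None, 1),
         (80_000, 53_000, 4), (132_500, 53_000, 3), (530_000, 53_000, 2),
         (106_000, 53_000, 4), (159_000, 53_000, 3)],
    )
    def test_cost_effectiveness_ratio_bands(self, icer, gdp, code):
        assert code_cost_effectiveness(icer, gdp) == code

    def test_icer_without_gdp_rejected(self):
        with pytest.raises(InvalidInputError):
            code_cost_effectiveness(1000, None)
        with pytest.raises(InvalidInputError):
            code_cost_effectiveness(1000, 0)

    @pytest.mark.parametrize(
        "prob, code", [(None, 1), (30, 2), (50, 3), (60, 3), (75, 3),
                       (76, 4), (99, 4), (100, 5)]
    )
    def test_financial_protection_bands(self, prob, code):
        assert code_financial_protection(prob) == code


class TestQualitativeRubrics:
    @pytest.mark.parametrize(
        "level, code",
        [("partial availability", 5), ("relatively appropriate availability", 4),
         ("appropriate availability", 3), ("high availability", 2),
         ("very high availability", 1)],
    )
    def test_alternatives_levels(self, level, code):
        assert code_alternatives_availability(level) == code

    def test_alternatives_closed_vocabulary(self):
        with pytest.raises(InvalidInputError):
            code_alternatives_availability("plentiful")

    @pytest.mark.parametrize(
        "category, code",
        [("systematic-review-rct-high", 5), ("hta-high", 5),
         ("systematic-review-rct-medium-low", 4), ("rct-high", 3),
         ("cohort", 2), ("other", 1)],
    )
    def test_evidence_quality_categories(self, category, code):
        assert code_evidence_quality(category) == code

    @pytest.mark.parametrize(
        "level, code",
        [(None, 1), ("significant savings", 5), ("moderate savings", 4),
         ("very slight change in the amount of savings", 3),
         ("no significant changes in the costs", 2)],
    )
    def test_budget_impact_levels(self, level, code):
        assert code_budget_impact(level) == code


class TestTotalityAndMonotonicity:
    def test_exactly_one_code_everywhere_on_numeric_domains(self):
        # dense scans across each numeric domain: the rubric is total and
        # returns a single integer code in 1..5 at every point
        for n in np.linspace(0, 2e6, 4001):
            assert code_population_size(n) in range(1, 6)
        for x in np.linspace(0, 100, 2001):
            assert code_safety(incidence=x) in range(1, 6)
            assert code_vulnerable_share(x) in range(1, 6)
            assert code_financial_protection(x) in range(1, 6)
        for r in np.linspace(0, 5, 1001):
            assert code_cost_effectiveness(r * 1000, 1000) in range(1, 6)

    def test_monotone_where_ordered(self):
        pops = [code_population_size(n) for n in np.linspace(0, 1e6, 2001)]
        assert pops == sorted(pops)
        vuln = [code_vulnerable_share(x) for x in np.linspace(0, 100, 1001)]
        assert vuln == sorted(vuln)
        fin = [code_financial_protection(x) for x in np.linspace(0, 100, 1001)]
        assert fin == sorted(fin)
        # lower ICER ratio never yields a lower code
        ratios = [code_cost_effectiveness(r * 1000, 1000)
                  for r in np.linspace(0.01, 5, 1001)]
        assert ratios == sorted(ratios, reverse=True)
        safety = [code_safety(incidence=x) for x in np.linspace(0, 100, 1001)]
        assert safety == sorted(safety, reverse=True)


class TestPilotRoundTrip:
    def test_profiles_code_to_published_matrix(self, pilot_profiles, pilot_matrix):
        coded = build_decision_matrix(pilot_profiles)
        assert coded.alternatives == pilot_matrix.alternatives
        assert coded.criteria == pilot_matrix.criteria
        np.testing.assert_array_equal(coded.values, pilot_matrix.values)

    def test_provenance_names_fired_bands(self, pilot_profiles):
        row = code_profile(pilot_profiles[0])
        assert row.codes == (5, 4, 4, 4, 2, 1, 1, 1, 5)
        assert row.provenance["cost_effectiveness"] == "unspecified"
        assert "perfect treatment" in row.provenance["efficiency_effectiveness"]

    def test_empty_profile_list_gives_empty_matrix(self):
        matrix = build_decision_matrix([])
        assert matrix.values.shape == (0, 9)

    def test_missing_safety_evidence_is_an_error(self, pilot_profiles):
        broken = EvidenceProfile(**{**pilot_profiles[0].to_dict(),
                                    "safety_level": None, "safety_incidence": None})
        with pytest.raises(InvalidInputError, match="safety"):
            code_profile(broken)

    def test_custom_rubrics_are_honored(self, pilot_profiles):
        rb = default_rubrics()
        cfg = {k: (dict(v) if isinstance(v, dict) else list(v))
               for k, v in rb.config.items()}
        cfg["population_size"] = {"bands": [], "else": 3}
        from htaprio.rubrics import Rubrics

        custom = Rubrics(cfg)
        assert custom.code_population_size(180_000).code == 3
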