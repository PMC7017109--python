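"""Matching-score unit and property tests, including brute-force oracle
equivalence on random toy problems."""

import itertools

import pytest

from oncomatch import (
    ConfigurationError,
    DrugRecord,
    EmptyProfileError,
    KnowledgeBase,
    MatchRule,
    MolecularAlteration,
    PatientProfile,
    Regimen,
    ScoringConfig,
    drug_hits,
    matching_score,
    regimen_hit_score,
)
from oncomatch.scoring import round_half_up

from conftest import brute_force_score, random_toy_problem


class TestWorkedExample:
    """The published hormone-positive breast-cancer case: 6 biomarkers,
    tamoxifen 17%, anastrozole+everolimus 42%, unmatched cytotoxics 0%."""

    @pytest.mark.parametrize(
        "regimen,expected",
        [
            ("tamoxifen", 17),
            ("anastrozole+everolimus", 42),
            ("fluorouracil+doxorubicin+cyclophosphamide", 0),
            ("capecitabine", 0),
            ("cisplatin", 0),
            ("paclitaxel", 0),
        ],
    )
    def test_published_scores(self, kb, p51, regimen, expected):
        assert matching_score(regimen, p51, kb).score_percent == expected

    def test_tamoxifen_hits_er_only(self, kb, p51):
        hits = drug_hits("tamoxifen", p51, kb)
        assert set(hits) == {("ER", "expression_positive")}
        assert hits[("ER", "expression_positive")].contribution == 1.0

    def test_capecitabine_hits_nothing(self, kb, p51):
        assert drug_hits("capecitabine", p51, kb) == {}

    def test_everolimus_hits_pten(self, kb, p51):
        hits = drug_hits("everolimus", p51, kb)
        assert set(hits) == {("PTEN", "copy_loss")}

    def test_combination_breakdown(self, kb, p51):
        bd = regimen_hit_score(Regimen.parse("anastrozole+everolimus"), p51, kb)
        assert bd.numerator == 2.5
        assert bd.denominator == 6
        assert bd.capped[("ER", "expression_positive")] == 1.0
        assert bd.capped[("PR", "expression_positive")] == 0.5
        assert bd.capped[("PTEN", "copy_loss")] == 1.0


class TestAggregation:
    def _er_kb(self):
        rule = lambda d: MatchRule(
            d, "ER", "expression_positive", "direct",
            evidence_tag="sensitivity_biomarker",
        )
        return KnowledgeBase(
            drugs=(DrugRecord("d1"), DrugRecord("d2")),
            rules=(rule("d1"), rule("d2")),
        )

    def _er_profile(self):
        return PatientProfile(
            "x", alterations=(MolecularAlteration("ER", "expression_positive"),)
        )

    def test_cap_prevents_double_counting(self):
        bd = regimen_hit_score(
            Regimen.parse("d1+d2"), self._er_profile(), self._er_kb()
        )
        assert bd.capped[("ER", "expression_positive")] == 1.0
        assert bd.numerator == 1.0

    def test_full_coverage_scores_100(self):
        result = matching_score("d1", self._er_profile(), self._er_kb())
        assert result.score_percent == 100

    def test_no_rules_numerator_zero(self, kb, p51):
        bd = regimen_hit_score(Regimen.parse("capecitabine+cisplatin"), p51, kb)
        assert bd.numerator == 0

    def test_empty_profile_is_an_error(self, kb):
        empty = PatientProfile("e", alterations=())
        with pytest.raises(EmptyProfileError):
            matching_score("tamoxifen", empty, kb)
        negative_only = PatientProfile(
            "n", alterations=(MolecularAlteration("ERBB2", "expression_negative"),)
        )
        with pytest.raises(EmptyProfileError):
            matching_score("tamoxifen", negative_only, kb)

    def test_resistance_nullifies_whole_drug(self):
        kb = KnowledgeBase(
            drugs=(DrugRecord("d1"),),
            rules=(
                MatchRule("d1", "ER", "expression_positive", "direct",
                          evidence_tag="sensitivity_biomarker"),
                MatchRule("d1", "KRAS", "mutation_activating", "resistance"),
            ),
        )
        sensitive = PatientProfile(
            "s", alterations=(MolecularAlteration("ER", "expression_positive"),)
        )
        resistant = PatientProfile(
            "r",
            alterations=(
                MolecularAlteration("ER", "expression_positive"),
                MolecularAlteration("KRAS", "mutation_activating"),
            ),
        )
        assert matching_score("d1", sensitive, kb).score_percent == 100
        assert matching_score("d1", resistant, kb).score_percent == 0

    def test_weight_override_replaces_default(self):
        kb = KnowledgeBase(
            drugs=(DrugRecord("d1"),),
            rules=(
                MatchRule("d1", "ER", "expression_positive", "direct",
                          weight_override=0.8,
                          evidence_tag="sensitivity_biomarker"),
            ),
        )
        prof = PatientProfile(
            "x", alterations=(MolecularAlteration("ER", "expression_positive"),)
        )
        assert matching_score("d1", prof, kb).score_percent == 80


class TestModifiers:
    def test_no_modifiers_identity(self, kb, p51):
        result = matching_score("tamoxifen", p51, kb)
        assert result.modifiers_applied == ()

    def test_pediatric_vs_adult_only_drug_zeroes(self):
        kb = KnowledgeBase(
            drugs=(DrugRecord("d1", adult_only=True),),
            rules=(
                MatchRule("d1", "ER", "expression_positive", "direct",
                          evidence_tag="sensitivity_biomarker"),
            ),
        )
        child = PatientProfile(
            "c",
            age_class="pediatric",
            alterations=(MolecularAlteration("ER", "expression_positive"),),
        )
        config = ScoringConfig(modifiers_enabled=("eligibility_zero",))
        result = matching_score("d1", child, kb, config)
        assert result.score_percent == 0
        assert result.modifiers_applied == (("eligibility_zero", 0.0),)

    def test_allergy_and_route_mismatch_zero(self, kb, p51):
        config = ScoringConfig(modifiers_enabled=("eligibility_zero",))
        allergic = PatientProfile(
            "a", alterations=p51.alterations, allergies={"tamoxifen"}
        )
        assert matching_score("tamoxifen", allergic, kb, config).score_percent == 0
        oral_only = PatientProfile(
            "o", alterations=p51.alterations, accepted_routes={"oral"}
        )
        # trastuzumab is iv-only in the fixture
        assert matching_score("trastuzumab", oral_only, kb, config).score_percent == 0

    def test_single_factor_applied_before_rounding(self):
        kb = KnowledgeBase(
            drugs=(DrugRecord("d1"), DrugRecord("d2")),
            rules=(
                MatchRule("d1", "ER", "expression_positive", "direct",
                          evidence_tag="sensitivity_biomarker"),
            ),
        )
        prof = PatientProfile(
            "x",
            alterations=(
                MolecularAlteration("ER", "expression_positive"),
                MolecularAlteration("KRAS", "mutation_activating"),
            ),
        )
        # ratio 0.5, one extra drug at penalty 0.9 -> 45
        config = ScoringConfig(
            modifiers_enabled=("drug_count_penalty",), drug_count_penalty=0.9
        )
        assert matching_score("d1+d2", prof, kb, config).score_percent == 45

    def test_unknown_modifier_id_rejected(self, kb, p51):
        config = ScoringConfig(modifiers_enabled=("no_such_modifier",))
        with pytest.raises(ConfigurationError):
            matching_score("tamoxifen", p51, kb, config)


class TestInvariantsAndOracle:
    @pytest.mark.parametrize("seed", range(40))
    def test_brute_force_oracle_equivalence(self, seed):
        """Random toy KBs: the implementation must agree with a naive
        independently-coded evaluator for every regimen of size <= 3."""
        kb, profile = random_toy_problem(seed)
        ids = kb.drug_ids
        for k in (1, 2, 3):
            for combo in itertools.combinations(ids, k):
                expected = brute_force_score(combo, profile, kb)
                got = matching_score(combo, profile, kb).score_percent
                assert got == expected, (seed, combo)

    @pytest.mark.parametrize("seed", range(12))
    def test_bounds_and_zero_iff_no_hits(self, seed):
        kb, profile = random_toy_problem(seed)
        for drug in kb.drug_ids:
            result = matching_score(drug, profile, kb)
            assert 0 <= result.score_percent <= 100
            assert (result.score_percent == 0) == (result.breakdown.numerator == 0)

    @pytest.mark.parametrize("seed", range(12))
    def test_adding_a_drug_never_decreases_score(self, seed):
        kb, profile = random_toy_problem(seed, with_resistance=False)
        ids = kb.drug_ids
        for combo in itertools.combinations(ids, 2):
            s_pair = matching_score(combo, profile, kb).score_percent
            for d in combo:
                assert s_pair >= matching_score((d,), profile, kb).score_percent

    def test_permutation_invariance(self, kb, p51):
        drugs = ["anastrozole", "everolimus", "tamoxifen"]
        scores = {
            matching_score("+".join(perm), p51, kb).score_percent
            for perm in itertools.permutations(drugs)
        }
        assert len(scores) == 1

    def test_case_insensitive_drug_tokens(self, kb, p51):
        assert matching_score("TAMOXIFEN", p51, kb).score_percent == 17


class TestConfigAndRounding:
    @pytest.mark.parametrize(
        "x,expected", [(16.5, 17), (41.666666, 42), (0.49999, 0), (99.5, 100),
                       (41.5, 42)]
    )
    def test_round_half_up(self, x, expected):
        assert round_half_up(x) == expected

    def test_invalid_weight_ordering_rejected(self):
        with pytest.raises(ConfigurationError):
            ScoringConfig(direct_weight=0.4, indirect_weight=0.5)

    def test_empty_regimen_rejected(self):
        with pytest.raises(ConfigurationError):
            Regimen(frozenset())
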