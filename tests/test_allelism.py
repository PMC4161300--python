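import dataclasses
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmisnowball import presets
from dmisnowball.allelism import (
    AllelismError,
    GenotypeStats,
    classify_allelism,
    effect_size_delta,
    estimate_additional_effect,
    estimate_shared_effect,
    fit_group_stats,
    run_allelism_test,
)
from dmisnowball.synth import FertilityScenario, gen_fertility


def _stats(letter_map, means):
    return [
        GenotypeStats(genotype=g, ls_mean=means[g], group_labels=frozenset(letters), n=25)
        for g, letters in letter_map.items()
    ]


class TestClassification:
    """The rule table applied to the published letter displays."""

    def test_pf72_letters_give_homologous(self):
        stats = _stats(
            {"SL": "A", "IL_PP": "B", "IL_HH": "B", "IL_HP": "B", "IL_PH": "B"},
            presets.TABLE2_MEANS["pf7.2"],
        )
        assert classify_allelism(stats).call == "homologous"

    def test_sss21_letters_give_sp_specific(self):
        stats = _stats(
            {"SL": "A", "IL_PP": "B", "IL_HH": "A", "IL_HP": "A"},
            presets.TABLE2_MEANS["sss2.1"],
        )
        assert classify_allelism(stats).call == "lineage_specific_SP"

    def test_sss12_letters_give_composite(self):
        stats = _stats(
            {"SL": "A", "IL_PP": "C", "IL_HH": "B", "IL_HP": "B"},
            presets.TABLE2_MEANS["sss1.2"],
        )
        assert classify_allelism(stats).call == "composite_shared_plus_SP"

    def test_uniform_letters_give_no_sterility(self):
        stats = _stats(
            {"SL": "A", "IL_PP": "A", "IL_HH": "A", "IL_HP": "A"},
            {"SL": 60.0, "IL_PP": 59.0, "IL_HH": 61.0, "IL_HP": 60.5},
        )
        assert classify_allelism(stats).call == "no_sterility"

    def test_mirror_case_sh_specific(self):
        stats = _stats(
            {"SL": "A", "IL_PP": "A", "IL_HH": "B", "IL_HP": "A"},
            {"SL": 60.0, "IL_PP": 62.0, "IL_HH": 11.0, "IL_HP": 61.0},
        )
        assert classify_allelism(stats).call == "lineage_specific_SH"

    def test_rescue_allows_overshooting_sl(self):
        # trans-heterozygote significantly MORE fertile than SL still rescues
        stats = _stats(
            {"SL": "B", "IL_PP": "C", "IL_HH": "AB", "IL_HP": "A"},
            {"SL": 60.0, "IL_PP": 11.0, "IL_HH": 64.0, "IL_HP": 68.0},
        )
        assert classify_allelism(stats).call == "lineage_specific_SP"

    def test_unresolvable_pattern_is_indeterminate(self):
        stats = _stats(
            {"SL": "A", "IL_PP": "B", "IL_HH": "C", "IL_HP": "D"},
            {"SL": 60.0, "IL_PP": 40.0, "IL_HH": 25.0, "IL_HP": 10.0},
        )
        assert classify_allelism(stats).call == "indeterminate"

    def test_missing_required_genotype_errors(self):
        stats = _stats({"SL": "A", "IL_PP": "B"}, {"SL": 60.0, "IL_PP": 10.0})
        with pytest.raises(AllelismError, match="IL_HH"):
            classify_allelism(stats)


class TestGroupStats:
    def test_null_case_shares_one_letter(self):
        scenario = FertilityScenario(
            genotype_means={g: 50.0 for g in ("SL", "IL_HH", "IL_PP", "IL_HP", "IL_PH")},
            sd=8.0,
            trait="seed",
            n_per_class=30,
            families_per_class=5,
        )
        fit = fit_group_stats(gen_fertility(scenario, seed=4), "seed")
        common = frozenset.intersection(*[s.group_labels for s in fit.stats])
        assert common, "equal true means should share a Tukey letter"

    def test_two_distant_classes_fully_separated(self):
        scenario = FertilityScenario(
            genotype_means={"SL": 10.0, "IL_PP": 0.0},
            sd=0.1,
            trait="seed",
            n_per_class=25,
            families_per_class=1,
        )
        fit = fit_group_stats(gen_fertility(scenario, seed=0), "seed")
        by_g = fit.by_genotype()
        assert not by_g["SL"].shares_letter(by_g["IL_PP"])
        assert fit.anova_p_genotype < 1e-6

    def test_published_sss21_letter_pattern_at_experiment_noise(self):
        # at the experiment-scale error variance the published display
        # {SL:A, IL_PP:B, IL_HH:A, IL_HP:A} is the typical outcome
        scenario = presets.fertility_scenario("sss2.1")
        fit = fit_group_stats(gen_fertility(scenario, seed=1), "seed")
        by_g = fit.by_genotype()
        assert not by_g["IL_PP"].shares_letter(by_g["SL"])
        assert by_g["IL_HH"].shares_letter(by_g["SL"])
        assert by_g["IL_HP"].shares_letter(by_g["IL_HH"])

    def test_single_class_errors(self):
        scenario = FertilityScenario(
            genotype_means={"SL": 50.0}, sd=1.0, trait="seed", n_per_class=5,
            families_per_class=1,
        )
        with pytest.raises(AllelismError):
            fit_group_stats(gen_fertility(scenario, seed=0), "seed")

    def test_maternal_effects_reported(self):
        scenario = presets.fertility_scenario("sss1.2")
        fit = fit_group_stats(gen_fertility(scenario, seed=0), "seed")
        assert np.isfinite(fit.maternal_p)


class TestObservedMeansEmulation:
    """Simulations at the published class means reproduce the published
    calls as the modal determinate outcome."""

    @pytest.mark.parametrize("locus", sorted(presets.TABLE2_MEANS))
    def test_published_call_is_modal_determinate(self, locus):
        scenario = presets.fertility_scenario(locus)
        calls = Counter(
            run_allelism_test(gen_fertility(scenario, seed=s), scenario.trait)[1].call
            for s in range(30)
        )
        determinate = {c: n for c, n in calls.items() if c != "indeterminate"}
        assert determinate
        assert max(determinate, key=determinate.get) == presets.ALLELISM_CALLS[locus]


class TestEffectSizes:
    def test_sss12_delta_matches_published(self):
        assert effect_size_delta(60.83, 10.41) == pytest.approx(-82.9, abs=0.05)

    def test_equal_means_give_zero(self):
        assert effect_size_delta(42.0, 42.0) == 0.0

    def test_pooled_pollen_delta(self):
        assert effect_size_delta(0.9, 0.78) == pytest.approx(-13.3, abs=0.05)

    def test_nonpositive_sl_mean_errors(self):
        with pytest.raises(AllelismError):
            effect_size_delta(0.0, 1.0)

    @given(st.floats(0.0, 100.0), st.floats(0.0, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_il_mean(self, a, b):
        lo, hi = sorted((a, b))
        assert effect_size_delta(60.0, lo) <= effect_size_delta(60.0, hi)

    def test_shared_effect_matches_published_47pct_28_seeds(self):
        delta, seeds = estimate_shared_effect(60.83, 38.13, 26.66)
        assert delta == pytest.approx(-46.7, abs=0.05)
        assert round(delta) == -47
        assert seeds == pytest.approx(28.4, abs=0.05)
        assert round(seeds) == 28

    def test_shared_effect_trivial_and_hand_cases(self):
        assert estimate_shared_effect(100.0, 100.0, 100.0) == (0.0, 0.0)
        assert estimate_shared_effect(50.0, 30.0, 20.0) == (pytest.approx(-50.0), pytest.approx(25.0))

    def test_additional_effect_matches_published_68pct(self):
        pool = (38.13 + 26.66) / 2
        assert estimate_additional_effect(10.41, pool) == pytest.approx(-67.9, abs=0.05)
        assert round(estimate_additional_effect(10.41, pool)) == -68

    def test_additional_effect_trivial_and_hand_cases(self):
        assert estimate_additional_effect(40.0, 40.0) == 0.0
        assert estimate_additional_effect(10.0, 40.0) == pytest.approx(-75.0)

    @given(
        st.floats(1.0, 100.0),
        st.floats(0.1, 100.0),
        st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_sequential_composition_reconstructs_il_pp(self, sl, pool, il_pp):
        """Applying the shared then the additional reduction to SL must
        reproduce the IL_PP mean exactly (multiplicative composition)."""
        shared, _ = estimate_shared_effect(sl, pool, pool)
        additional = estimate_additional_effect(il_pp, pool)
        reconstructed = sl * (1 + shared / 100.0) * (1 + additional / 100.0)
        assert reconstructed == pytest.approx(il_pp, rel=1e-9)
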