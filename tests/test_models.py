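import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dmisnowball.combinatorics import per_focal_new_triples
from dmisnowball.models import (
    BasisCache,
    ModelError,
    compare_models,
    expected_counts,
    fit_model,
    loglik,
    loglik_total_multinomial,
    make_model,
    triple_mc_basis,
)
from dmisnowball.placement import BranchCounts
from dmisnowball.selection import calibrate_params, simulate_counts
from dmisnowball.tables import RunConfig
from dmisnowball.trees import ThreeTaxonTree, TreeSet, enforce_clock

POLLEN = BranchCounts(trait="pollen", n_b=1, n_c=7, n_d=6)


class TestExpectedCounts:
    def test_zero_params_zero_means(self, solanum_tree):
        for name, k in (("linear", 1), ("DM", 1), ("paPd", 2)):
            mu = expected_counts(make_model(name, *([0.0] * k)), solanum_tree)
            assert mu.as_array().tolist() == [0.0, 0.0, 0.0]

    def test_linear_means_proportional_to_branch_lengths(self, solanum_tree):
        mu = expected_counts(make_model("linear", 1.0), solanum_tree)
        assert mu.mu_b / mu.total == pytest.approx(0.251)
        assert mu.mu_c == mu.mu_d

    def test_dm_closed_form_matches_monte_carlo_oracle(self, solanum_tree):
        """Independent MC estimate of the DM mean: simulate substitution
        histories and accumulate the per-substitution potential-interaction
        weight (T derived-derived budget + #prior own-lineage substitutions)."""
        rng = np.random.default_rng(5)
        T = solanum_tree.depth_T
        reps = 20000
        mc = np.zeros(2)  # branch b, one terminal
        for _ in range(reps):
            K1 = rng.poisson(T)
            if K1 == 0:
                continue
            depths = np.sort(rng.uniform(0, T, K1))
            K2 = rng.poisson(solanum_tree.t_a)
            for i, u in enumerate(depths):
                weight = K2 + i  # dd partners + da partners (i prior subs)
                mc[0 if u <= solanum_tree.t_b else 1] += weight
        mc /= reps
        mu = expected_counts(make_model("DM", 1.0), solanum_tree)
        assert mc[0] == pytest.approx(mu.mu_b, rel=0.02)
        assert mc[1] == pytest.approx(mu.mu_c, rel=0.02)

    def test_papd_reduces_to_dm_when_rates_equal(self, solanum_tree):
        dm = expected_counts(make_model("DM", 2.5), solanum_tree)
        papd = expected_counts(make_model("paPd", 2.5, 2.5), solanum_tree)
        assert papd.as_array() == pytest.approx(dm.as_array())

    def test_p2p3_reduces_to_dm_when_c3_zero(self, solanum_tree, config):
        dm = expected_counts(make_model("DM", 2.5), solanum_tree, config=config)
        p23 = expected_counts(make_model("p2p3", 2.5, 0.0), solanum_tree, config=config)
        assert p23.as_array() == pytest.approx(dm.as_array())

    def test_non_ultrametric_tree_rejected(self):
        skewed = ThreeTaxonTree(t_a=1.0, t_b=0.4, t_c=0.2, t_d=0.9)
        with pytest.raises(ModelError, match="ultrametric"):
            expected_counts(make_model("linear", 1.0), skewed)

    @given(
        st.floats(0.01, 5.0),
        st.floats(0.01, 5.0),
        st.floats(0.1, 3.0),
        st.floats(0.1, 3.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_means_monotone_in_params_and_lengths(self, p1, p2, t_b, t_c):
        tree = enforce_clock(ThreeTaxonTree(t_a=t_b + t_c, t_b=t_b, t_c=t_c, t_d=t_c))
        bigger_tree = enforce_clock(
            ThreeTaxonTree(t_a=t_b + t_c + 0.5, t_b=t_b + 0.25, t_c=t_c + 0.25, t_d=t_c + 0.25)
        )
        for name in ("linear", "DM", "paPd"):
            k = 1 if name in ("linear", "DM") else 2
            lo = make_model(name, *([p1] * k))
            hi = make_model(name, *([p1 + p2] * k))
            mu_lo = expected_counts(lo, tree).as_array()
            mu_hi = expected_counts(hi, tree).as_array()
            assert np.all(mu_hi >= mu_lo)
            assert np.all(expected_counts(lo, bigger_tree).as_array() >= mu_lo)

    def test_snowball_total_superlinear_in_depth(self, solanum_tree):
        model = make_model("DM", 1.0)
        mu_T = expected_counts(model, solanum_tree).total
        mu_2T = expected_counts(model, solanum_tree.scaled(2.0)).total
        assert mu_2T > 2 * mu_T

    def test_dm_early_fraction_below_linear(self, solanum_tree):
        lin = expected_counts(make_model("linear", 1.0), solanum_tree)
        dm = expected_counts(make_model("DM", 1.0), solanum_tree)
        assert dm.mu_b / dm.total < lin.mu_b / lin.total


class TestTripleTerm:
    def test_mc_matches_analytic_integral(self, solanum_tree):
        """E[sum over branch foci of trios completed] has the closed form
        integral of (u * t_a + u^2 / 2) over the branch's depth interval."""
        m3 = triple_mc_basis(solanum_tree, mc_reps=40000, seed=2)
        T, t_a, t_b = solanum_tree.depth_T, solanum_tree.t_a, solanum_tree.t_b

        def integral(u0, u1):
            return t_a * (u1**2 - u0**2) / 2 + (u1**3 - u0**3) / 6

        assert m3[0] == pytest.approx(integral(0, t_b), rel=0.05)
        assert m3[1] == pytest.approx(integral(t_b, T), rel=0.05)
        assert m3[1] == m3[2]

    def test_seeded_reproducibility(self, solanum_tree):
        a = triple_mc_basis(solanum_tree, mc_reps=2000, seed=9)
        b = triple_mc_basis(solanum_tree, mc_reps=2000, seed=9)
        assert np.array_equal(a, b)

    def test_first_substitution_completes_nothing(self):
        assert per_focal_new_triples(1, 10) == 0


class TestLoglik:
    def test_empty_data_zero_mean_convention(self, solanum_tree):
        counts = BranchCounts(trait="pollen", n_b=0, n_c=0, n_d=0)
        assert loglik(make_model("linear", 0.0), counts, solanum_tree) == 0.0

    def test_matches_total_multinomial_decomposition(self, solanum_tree):
        """The per-branch Poisson likelihood equals the per-pair-totals
        factorization (Poisson total x multinomial split) exactly."""
        for c in (0.5, 2.0, 3.55):
            model = make_model("DM", c)
            assert loglik(model, POLLEN, solanum_tree) == pytest.approx(
                loglik_total_multinomial(model, POLLEN, solanum_tree), rel=1e-12
            )

    def test_zero_mean_with_observed_count_is_minus_inf(self, solanum_tree):
        assert loglik(make_model("linear", 0.0), POLLEN, solanum_tree) == -np.inf

    def test_perturbing_mle_mean_decreases_loglik(self, solanum_tree):
        # concavity: rho at the closed-form MLE beats neighbours
        rho_hat = POLLEN.n_total / solanum_tree.total_bcd
        best = loglik(make_model("linear", rho_hat), POLLEN, solanum_tree)
        for factor in (0.8, 0.95, 1.05, 1.2):
            assert loglik(make_model("linear", rho_hat * factor), POLLEN, solanum_tree) < best


class TestFitting:
    def test_linear_mle_matches_closed_form(self, solanum_tree, config):
        fit = fit_model("linear", POLLEN, solanum_tree, config=config)
        assert fit.model.params["rho"] == pytest.approx(
            POLLEN.n_total / solanum_tree.total_bcd, rel=1e-4
        )

    def test_parameter_recovery_linear_at_scale(self, solanum_tree, config):
        spec = calibrate_params("linear", solanum_tree, 1500.0)
        errors = []
        for seed in range(30):
            counts = simulate_counts(spec, solanum_tree, seed=seed)
            fit = fit_model("linear", counts, solanum_tree, config=config)
            errors.append(abs(fit.model.params["rho"] - spec.params["rho"]) / spec.params["rho"])
        assert np.median(errors) < 0.05

    def test_nested_models_dominate_dm(self, solanum_tree, config):
        """DM is the c3=0 / c_a=c_d boundary of both 2-parameter models, so
        their maximized log likelihoods can never fall below DM's."""
        cache = BasisCache(config)
        for counts in (POLLEN, BranchCounts(trait="seed", n_b=1, n_c=3, n_d=4)):
            ll_dm = fit_model("DM", counts, solanum_tree, config=config, basis_cache=cache).loglik
            for name in ("p2p3", "paPd"):
                ll = fit_model(name, counts, solanum_tree, config=config, basis_cache=cache).loglik
                assert ll >= ll_dm - 1e-6

    def test_single_tree_has_zero_aic_sd(self, solanum_tree, config):
        fit = fit_model("DM", POLLEN, solanum_tree, config=config)
        assert fit.aic_sd == 0.0
        assert fit.n_trees == 1

    def test_aic_identity(self, solanum_tree, config):
        fit = fit_model("DM", POLLEN, solanum_tree, config=config)
        assert fit.aic == pytest.approx(2 * fit.model.k - 2 * fit.loglik)

    def test_tree_set_propagates_variance(self, solanum_tree, config):
        from dmisnowball.synth import gen_tree_set

        trees = gen_tree_set(solanum_tree, cv=0.15, n=8, seed=3)
        fit = fit_model("DM", POLLEN, trees, config=config)
        assert fit.aic_sd > 0
        assert fit.n_trees == 8


class TestComparison:
    def test_selection_consistent_under_linear_truth(self, solanum_tree, config):
        spec = calibrate_params("linear", solanum_tree, 1200.0)
        counts = simulate_counts(spec, solanum_tree, seed=0)
        result = compare_models(counts, solanum_tree, config=config)
        assert result.selected == "linear"

    def test_dm_truth_never_selects_linear(self, solanum_tree, config):
        spec = calibrate_params("DM", solanum_tree, 1200.0)
        for seed in range(5):
            counts = simulate_counts(spec, solanum_tree, seed=seed)
            result = compare_models(counts, solanum_tree, config=config)
            assert result.selected != "linear"

    def test_pollen_counts_reject_linear(self, solanum_tree, config):
        result = compare_models(POLLEN, solanum_tree, config=config)
        others = [f.aic for name, f in result.fits.items() if name != "linear"]
        assert result.fits["linear"].aic - min(others) > 0
        assert result.selected != "linear"

    def test_table_contains_all_models(self, solanum_tree, config):
        table = compare_models(POLLEN, solanum_tree, config=config).table()
        assert set(table["model"]) == {"linear", "DM", "p2p3", "paPd"}
        assert table["selected"].sum() == 1
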