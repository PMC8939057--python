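import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from raschshort import pcm, synthetic as syn
from conftest import make_response_matrix
from oracles import brute_force_cml, enumerate_conditional_probability, grid_person_mle


class TestCategoryProbabilities:
    def test_symmetric_dichotomous_case(self):
        np.testing.assert_allclose(
            pcm.category_probabilities(0.0, np.array([0.0])), [0.5, 0.5]
        )

    def test_three_category_symmetric_item(self):
        # delta=0, tau=(-1, 1): category weights (1, e, 1)
        p = pcm.category_probabilities(0.0, np.array([-1.0, 1.0]))
        np.testing.assert_allclose(p, [0.212, 0.576, 0.212], atol=5e-4)

    def test_palindromic_at_item_location(self):
        beta = 0.7 + np.array([-1.3, -0.2, 0.2, 1.3])  # sign-palindromic tau
        p = pcm.category_probabilities(0.7, beta)
        np.testing.assert_allclose(p, p[::-1], atol=1e-12)

    def test_rejects_nonfinite_input(self):
        with pytest.raises(ValueError):
            pcm.category_probabilities(np.nan, np.array([0.0]))
        with pytest.raises(ValueError):
            pcm.category_probabilities(0.0, np.array([np.inf, 0.0]))

    @settings(max_examples=200, derandomize=True)
    @given(
        theta=st.floats(-30, 30),
        tau=st.lists(st.floats(-4, 4), min_size=1, max_size=6),
        delta=st.floats(-5, 5),
    )
    def test_normalisation_and_range(self, theta, tau, delta):
        p = pcm.category_probabilities(theta, delta + np.asarray(tau))
        assert abs(p.sum() - 1.0) < 1e-12
        assert (p >= 0).all()

    def test_monotone_likelihood_ratio_in_theta(self):
        beta = np.array([-0.5, 0.1, 0.9])
        thetas = np.linspace(-4, 4, 30)
        ratios = np.array(
            [pcm.category_probabilities(t, beta)[-1] /
             pcm.category_probabilities(t, beta)[0] for t in thetas]
        )
        assert (np.diff(ratios) > 0).all()


class TestExpectedScoreAndVariance:
    def test_floor_limit(self):
        e, w = pcm.expected_score_and_variance(-50.0, np.array([-1.0, 1.0]))
        assert e == pytest.approx(0.0, abs=1e-12)
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_bernoulli_half(self):
        e, w = pcm.expected_score_and_variance(0.0, np.array([0.0]))
        assert (e, w) == (pytest.approx(0.5), pytest.approx(0.25))

    def test_three_category_moments(self):
        e, w = pcm.expected_score_and_variance(0.0, np.array([-1.0, 1.0]))
        assert e == pytest.approx(1.0, abs=1e-12)
        assert w == pytest.approx(0.424, abs=5e-4)

    def test_expectation_increasing_in_theta(self):
        beta = np.array([-1.2, 0.3, 1.1, 2.0])
        es = [pcm.expected_score_and_variance(t, beta)[0] for t in np.linspace(-5, 5, 40)]
        assert (np.diff(es) > 0).all()


class TestConditionalPatternProbability:
    def test_single_item_is_certain(self):
        items = pcm.ItemParameters(["A"], [np.array([-0.4, 0.6])])
        for x in range(3):
            assert pcm.conditional_pattern_probability(items, [x]) == pytest.approx(1.0)

    def test_two_identical_dichotomous_items_split_evenly(self):
        items = pcm.ItemParameters(["A", "B"], [np.array([0.3]), np.array([0.3])])
        assert pcm.conditional_pattern_probability(items, [1, 0]) == pytest.approx(0.5)
        assert pcm.conditional_pattern_probability(items, [0, 1]) == pytest.approx(0.5)

    def test_matches_enumeration_and_sums_to_one(self):
        beta_list = [np.array([-0.7, 0.5]), np.array([0.2, 1.0]), np.array([-1.1, -0.1])]
        items = pcm.ItemParameters(["A", "B", "C"], beta_list)
        import itertools

        total_mass = {}
        for pat in itertools.product(range(3), repeat=3):
            p = pcm.conditional_pattern_probability(items, pat)
            assert p == pytest.approx(
                enumerate_conditional_probability(beta_list, pat), abs=1e-12
            )
            total_mass[sum(pat)] = total_mass.get(sum(pat), 0.0) + p
        for r, mass in total_mass.items():
            assert mass == pytest.approx(1.0, abs=1e-12)

    def test_invalid_pattern_rejected(self):
        items = pcm.ItemParameters(["A", "B"], [np.array([0.0]), np.array([0.0])])
        with pytest.raises(ValueError):
            pcm.conditional_pattern_probability(items, [2, 0])


class TestFitItemsCML:
    def test_matches_brute_force_oracle_on_small_instance(self):
        rng = np.random.default_rng(42)
        beta_true = [np.array([-0.6, 0.4]), np.array([0.0, 0.8]),
                     np.array([-0.9, -0.1]), np.array([0.3, 1.1])]
        theta = rng.normal(0, 1, 50)
        X = np.array(
            [[rng.choice(3, p=pcm.category_probabilities(t, b)) for b in beta_true]
             for t in theta]
        )
        # guarantee every category present in this tiny sample
        X[0] = [0, 0, 0, 0]
        X[1] = [1, 1, 1, 1]
        X[2] = [2, 2, 2, 2]
        rm = make_response_matrix(X)
        fit = pcm.fit_items_cml(rm)
        oracle = brute_force_cml(X, [2, 2, 2, 2])
        np.testing.assert_allclose(
            np.concatenate(fit.beta), np.concatenate(oracle), atol=1e-4
        )

    def test_uniform_pattern_set_gives_equal_locations(self):
        # all 8 dichotomous patterns equally weighted: perfect symmetry
        import itertools

        X = np.array(list(itertools.product([0, 1], repeat=3)))
        rm = make_response_matrix(X)
        fit = pcm.fit_items_cml(rm)
        np.testing.assert_allclose(fit.delta, 0.0, atol=1e-8)

    def test_identically_generated_items_agree(self):
        rng = np.random.default_rng(1)
        beta = np.array([-1.0, -0.2, 0.5, 1.2])
        theta = rng.normal(0, 1, 2000)
        X = np.column_stack(
            [syn._sample_categories(theta, beta, rng) for _ in range(2)]
            + [syn._sample_categories(theta, beta + s, rng) for s in (-0.5, 0.5)]
        )
        fit = pcm.fit_items_cml(make_response_matrix(X))
        assert abs(fit.delta[0] - fit.delta[1]) < 0.15

    def test_person_distribution_invariance(self):
        # the defining Rasch property: item estimates do not depend on the
        # ability distribution that generated the sample
        ids, betas = syn.unidimensional_item_bank(6, 2)
        fits = []
        for mean, sd, seed in ((-1.0, 0.7, 5), (0.8, 1.6, 6)):
            rng = np.random.default_rng(seed)
            theta = rng.normal(mean, sd, 4000)
            X = np.column_stack([syn._sample_categories(theta, b, rng) for b in betas])
            fits.append(pcm.fit_items_cml(make_response_matrix(X)))
        np.testing.assert_allclose(
            np.concatenate(fits[0].beta), np.concatenate(fits[1].beta), atol=0.25
        )

    def test_null_category_raises_named_error(self):
        X = np.array([[0, 1], [1, 0], [2, 1], [0, 0], [2, 1]])  # item2 never shows 2
        rm = make_response_matrix(X)
        rm.max_scores["I2"] = 2
        with pytest.raises(pcm.NullCategoryError, match="I2.*category 2"):
            pcm.fit_items_cml(rm)

    def test_centering_invariants(self, uni800):
        _, items, _ = uni800
        assert abs(items.delta.mean()) < 1e-10
        for tau in items.tau:
            assert abs(tau.sum()) < 1e-10


class TestEstimatePersons:
    def test_sufficiency_equal_totals_equal_estimates(self, uni800):
        rm, items, persons = uni800
        df = persons.persons
        grouped = df.groupby("total")[["theta", "se"]].nunique()
        assert (grouped <= 1).all().all()

    def test_strictly_increasing_in_total(self, uni800):
        _, _, persons = uni800
        theta = persons.score_table["theta"].to_numpy()
        assert (np.diff(theta) > 0).all()
        assert (persons.score_table["se"] > 0).all()

    def test_symmetric_items_give_antisymmetric_estimates(self):
        beta_list = [np.array([-1.0, 1.0]), np.array([-0.5, 0.5]), np.array([-1.5, 1.5])]
        items = pcm.ItemParameters(["A", "B", "C"], beta_list)
        table = pcm.score_to_theta(items)
        theta = table["theta"].to_numpy()
        np.testing.assert_allclose(theta, -theta[::-1], atol=1e-8)

    def test_interior_scores_match_grid_oracle(self):
        beta_list = [np.array([-0.8, 0.2]), np.array([-0.1, 0.9]), np.array([-0.4, 1.3])]
        items = pcm.ItemParameters(["A", "B", "C"], beta_list)
        table = pcm.score_to_theta(items)
        # any pattern with the given total yields the same ML theta (totals
        # are sufficient), so one pattern per total suffices for the oracle
        patterns = {1: [1, 0, 0], 3: [1, 1, 1], 5: [2, 2, 1]}
        for total, pat in patterns.items():
            oracle = grid_person_mle(pat, beta_list)
            assert table.loc[total, "theta"] == pytest.approx(oracle, abs=2e-3)

    def test_extreme_scores_get_finite_flagged_estimates(self, uni800):
        _, items, persons = uni800
        table = persons.score_table
        assert table.loc[0, "extreme"] and table.loc[items.max_total, "extreme"]
        assert np.isfinite(table["theta"]).all()


class TestParameterRecovery:
    def test_rmse_within_sampling_bounds(self):
        ids, betas = syn.unidimensional_item_bank(12, 4)
        true_delta = np.array([b.mean() for b in betas])
        true_tau = np.concatenate([b - b.mean() for b in betas])
        d_err, t_err = [], []
        for seed in range(3):
            rm = syn.simulate_unidimensional_pcm(
                syn.SyntheticSpec(n_persons=2000, person_mean=0.0, person_sd=1.0, seed=seed)
            )
            fit = pcm.fit_items_cml(rm)
            d_err.append(np.sqrt(np.mean((fit.delta - true_delta) ** 2)))
            t_err.append(
                np.sqrt(np.mean((np.concatenate(fit.tau) - true_tau) ** 2))
            )
        assert np.mean(d_err) < 0.1
        assert np.mean(t_err) < 0.25
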