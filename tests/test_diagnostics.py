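import numpy as np
import pandas as pd
import pytest

from raschshort import diagnostics as dg, pcm, synthetic as syn
from conftest import make_response_matrix


@pytest.fixture(scope="module")
def fitted(uni800):
    rm, items, persons = uni800
    E, W = dg.expected_and_variance_matrix(rm, items, persons)
    z = dg.standardized_residuals(rm, items, persons)
    return rm, items, persons, E, W, z


class TestStandardizedResiduals:
    def test_hand_computed_cell(self):
        # m=2, delta=0, tau=(-1,1), theta=0: E=1, W=0.424; x=2 -> 1.536
        e, w = pcm.expected_score_and_variance(0.0, np.array([-1.0, 1.0]))
        z = (2 - e) / np.sqrt(w)
        assert z == pytest.approx(1.536, abs=5e-4)

    def test_zero_when_data_equal_expectation(self):
        # symmetric 3-category items at theta=delta have integral E=1
        beta_list = [np.array([-1.0, 1.0])] * 4
        items = pcm.ItemParameters([f"I{i}" for i in range(4)], beta_list)
        X = np.ones((6, 4), dtype=int)
        X[0] = [0, 2, 1, 1]  # keep all categories observed, total still 4
        X[1] = [2, 0, 1, 1]
        rm = make_response_matrix(X, item_ids=items.item_ids)
        persons = pcm.estimate_persons(rm, items)
        z = dg.standardized_residuals(rm, items, persons)
        all_ones = z.index[(rm.scores == 1).all(axis=1)]
        assert np.allclose(z.loc[all_ones], 0.0, atol=1e-8)

    def test_grand_mean_near_zero_under_correct_model(self, fitted):
        *_, z = fitted
        assert abs(z.to_numpy().mean()) < 0.05

    def test_extreme_persons_excluded(self, fitted):
        rm, items, persons, *_ , z = fitted
        assert persons.persons["extreme"].sum() == len(rm.scores) - len(z)


class TestItemFitResiduals:
    def test_all_zero_residuals_give_maximal_overfit(self):
        z = pd.DataFrame(np.zeros((100, 5)), columns=list("ABCDE"))
        fr = dg.item_fit_residuals(z)
        assert (fr < -10).all()

    def test_null_distribution_envelope(self):
        means, sds = [], []
        for seed in range(5):
            rm = syn.simulate_unidimensional_pcm(
                syn.SyntheticSpec(n_persons=800, person_mean=0.0, person_sd=1.0, seed=30 + seed)
            )
            items = pcm.fit_items_cml(rm)
            persons = pcm.estimate_persons(rm, items)
            E, W = dg.expected_and_variance_matrix(rm, items, persons)
            z = dg.standardized_residuals(rm, items, persons)
            fr = dg.item_fit_residuals(z, W)
            means.append(fr.mean())
            sds.append(fr.std(ddof=1))
        assert -0.5 < np.mean(means) < 0.5
        assert 0.6 < np.mean(sds) < 1.6

    def test_overdiscriminating_item_is_most_negative(self):
        rng = np.random.default_rng(17)
        ids, betas = syn.unidimensional_item_bank(8, 4)
        theta = rng.normal(0, 1, 1500)
        cols = []
        for i, b in enumerate(betas):
            t = theta * 2.0 if i == 0 else theta  # item 0: doubled slope
            cols.append(syn._sample_categories(t, b, rng))
        rm = make_response_matrix(np.column_stack(cols), item_ids=ids)
        items = pcm.fit_items_cml(rm)
        persons = pcm.estimate_persons(rm, items)
        E, W = dg.expected_and_variance_matrix(rm, items, persons)
        z = dg.standardized_residuals(rm, items, persons)
        fr = dg.item_fit_residuals(z, W)
        assert fr.idxmin() == "I1" and fr["I1"] < 0


class TestItemTraitChiSquare:
    def test_null_calibration_ratio(self):
        ratios = []
        for seed in range(5):
            rm = syn.simulate_unidimensional_pcm(
                syn.SyntheticSpec(n_persons=800, person_mean=0.0, person_sd=1.0, seed=50 + seed)
            )
            items = pcm.fit_items_cml(rm)
            persons = pcm.estimate_persons(rm, items)
            _, tot = dg.item_trait_chi_square(rm, items, persons)
            ratios.append(tot["chi2"] / tot["df"])
        assert 0.7 < np.mean(ratios) < 1.4

    def test_misfitting_item_detected(self):
        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            rng = np.random.default_rng(70 + seed)
            ids, betas = syn.unidimensional_item_bank(8, 4)
            theta = rng.normal(0, 1, 800)
            cols = [
                syn._sample_categories(theta * (2.5 if i == 0 else 1.0), b, rng)
                for i, b in enumerate(betas)
            ]
            rm = make_response_matrix(np.column_stack(cols), item_ids=ids)
            items = pcm.fit_items_cml(rm)
            persons = pcm.estimate_persons(rm, items)
            table, _ = dg.item_trait_chi_square(rm, items, persons)
            hits += bool(table.loc["I1", "significant"])
        assert hits >= n_seeds - 1

    def test_df_and_interval_errors(self, fitted):
        rm, items, persons, *_ = fitted
        table, tot = dg.item_trait_chi_square(rm, items, persons, 8)
        assert (table["df"] == 7).all()
        assert tot["df"] == 7 * len(items.item_ids)
        with pytest.raises(ValueError):
            dg.item_trait_chi_square(rm, items, persons, 1)


class TestPersonSeparationIndex:
    def test_limits(self):
        df = pd.DataFrame(
            {"total": [1, 2, 3], "theta": [-1.0, 0.0, 1.0], "se": [0.0, 0.0, 0.0],
             "extreme": [False] * 3}
        )
        pe = pcm.PersonEstimates(persons=df, score_table=df.set_index("total"))
        assert dg.person_separation_index(pe) == pytest.approx(1.0)
        df2 = df.assign(se=np.sqrt(df["theta"].var(ddof=1)))
        pe2 = pcm.PersonEstimates(persons=df2, score_table=df2.set_index("total"))
        assert dg.person_separation_index(pe2) == pytest.approx(0.0, abs=1e-12)

    def test_shift_invariance(self, fitted):
        _, _, persons, *_ = fitted
        shifted = pcm.PersonEstimates(
            persons=persons.persons.assign(theta=persons.persons["theta"] + 3.7),
            score_table=persons.score_table,
        )
        assert dg.person_separation_index(shifted) == pytest.approx(
            dg.person_separation_index(persons)
        )

    def test_simulation_envelope(self):
        rm = syn.simulate_unidimensional_pcm(
            syn.SyntheticSpec(n_persons=800, person_mean=0.0, person_sd=1.5, seed=90)
        )
        items = pcm.fit_items_cml(rm)
        persons = pcm.estimate_persons(rm, items)
        assert 0.80 < dg.person_separation_index(persons) < 0.95


class TestResidualCorrelations:
    def test_unidimensional_average_near_minus_one_over_k(self, fitted):
        *_, z = fitted
        k = z.shape[1]
        rep = dg.residual_correlations(z)
        assert rep.average_offdiag == pytest.approx(-1.0 / (k - 1), abs=0.02)
        assert rep.critical == pytest.approx(0.2 - 1.0 / (k - 1), abs=0.02)

    def test_nineteen_item_critical_value(self):
        # k=19 unidimensional: critical ~ 0.2 - 1/18 ~ 0.145
        ids = [f"I{i}" for i in range(19)]
        betas = [np.linspace(-1, 1, 19)[i] + syn.DEFAULT_TAU for i in range(19)]
        rng = np.random.default_rng(3)
        theta = rng.normal(0, 1, 700)
        X = np.column_stack([syn._sample_categories(theta, b, rng) for b in betas])
        rm = make_response_matrix(X, item_ids=ids)
        items = pcm.fit_items_cml(rm)
        persons = pcm.estimate_persons(rm, items)
        z = dg.standardized_residuals(rm, items, persons)
        rep = dg.residual_correlations(z)
        assert rep.critical == pytest.approx(0.15, abs=0.02)

    def test_shared_nuisance_pair_flagged(self):
        rng = np.random.default_rng(8)
        ids, betas = syn.unidimensional_item_bank(10, 4)
        theta = rng.normal(0, 1, 800)
        extra = rng.normal(0, 0.8, 800)
        cols = [
            syn._sample_categories(theta + (extra if i < 2 else 0.0), b, rng)
            for i, b in enumerate(betas)
        ]
        rm = make_response_matrix(np.column_stack(cols), item_ids=ids)
        items = pcm.fit_items_cml(rm)
        persons = pcm.estimate_persons(rm, items)
        z = dg.standardized_residuals(rm, items, persons)
        rep = dg.residual_correlations(z)
        assert ("I1", "I2") in [(a, b) for a, b, _ in rep.flagged_pairs]

    def test_two_items_never_self_flag(self):
        rng = np.random.default_rng(0)
        z = pd.DataFrame(rng.normal(size=(50, 2)), columns=["A", "B"])
        rep = dg.residual_correlations(z)
        r = z["A"].corr(z["B"])
        assert rep.average_offdiag == pytest.approx(r)
        assert rep.critical == pytest.approx(r + 0.2)
        assert rep.flagged_pairs == []


class TestThresholdOrdering:
    @pytest.mark.parametrize(
        "tau, expected",
        [((-1.0, 0.0, 1.0), True), ((1.0, -1.0), False)],
    )
    def test_flags(self, tau, expected):
        items = pcm.ItemParameters(["A", "B"], [np.array(tau), np.array([-0.5, 0.5])])
        assert dg.check_threshold_ordering(items)["A"] == expected

    def test_ordered_generators_recovered(self, uni800):
        _, items, _ = uni800
        assert dg.check_threshold_ordering(items).all()


class TestSummaryFit:
    def test_fields_recompute_from_vectors(self, fitted):
        rm, items, persons, E, W, z = fitted
        rep = dg.summary_fit("TEST12", rm, items, persons)
        fr = dg.item_fit_residuals(z, W)
        assert rep.item_residual_mean == pytest.approx(fr.mean(), abs=1e-10)
        assert rep.item_residual_sd == pytest.approx(fr.std(ddof=1), abs=1e-10)
        assert rep.total_chi2 == pytest.approx(
            rep.item_table["chi2"].sum(), abs=1e-10
        )

    def test_deterministic_rerun(self, fitted):
        rm, items, persons, *_ = fitted
        a = dg.summary_fit("X", rm, items, persons).summary_row()
        b = dg.summary_fit("X", rm, items, persons).summary_row()
        assert a == b

    def test_summary_row_schema(self, fitted):
        rm, items, persons, *_ = fitted
        row = dg.summary_fit("X", rm, items, persons).summary_row()
        assert list(row) == [
            "analysis", "item_res_mean", "item_res_sd", "person_res_mean",
            "person_res_sd", "chisq", "chisq_p", "psi", "unidim_pct",
            "unidim_ci_low", "unidim_ci_high",
        ]
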