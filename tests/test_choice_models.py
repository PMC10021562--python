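"""Logit estimation: probabilities, likelihoods, gradients, MNL and MMNL fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tourpref as tp
from tourpref.choice_models import (
    CollinearityError,
    ColumnMismatchError,
    halton_normal_draws,
    mmnl_simulated_loglik,
    mnl_loglik,
)


def make_tiny_dataset(X, chosen, columns):
    """Assemble a ChoiceDataset from a (T, J, K) coded array and chosen indices."""
    T, J, K = X.shape
    rows = []
    for t in range(T):
        for j in range(J):
            rows.append(
                {
                    "respondent_id": t + 1,
                    "task_id": 1,
                    "alt_id": j + 1,
                    "chosen": int(j == chosen[t]),
                    "opt_out": 0,
                    **{c: X[t, j, k] for k, c in enumerate(columns)},
                }
            )
    return tp.ChoiceDataset(df=pd.DataFrame(rows), columns=list(columns))


class TestSystematicUtility:
    def test_zero_coefficients_give_zero(self):
        p = tp.UtilityParams(beta={"a": 0.0, "b": 0.0})
        assert tp.systematic_utility(p, [3.5, -2.0]) == 0.0

    def test_opt_out_constant_passes_through(self):
        p = tp.UtilityParams(beta={"condom_every": 1.7, "opt_out": 0.522})
        assert tp.systematic_utility(p, [0.0, 1.0]) == pytest.approx(0.522)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=8),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_equals_elementwise_sum_oracle(self, xs, seed):
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=len(xs))
        p = tp.UtilityParams(beta={f"c{i}": b for i, b in enumerate(beta)})
        oracle = sum(x * b for x, b in zip(xs, beta))
        assert tp.systematic_utility(p, xs) == pytest.approx(oracle, abs=1e-10)

    def test_column_mismatch_raises(self):
        p = tp.UtilityParams(beta={"a": 1.0})
        with pytest.raises(ColumnMismatchError):
            tp.systematic_utility(p, [1.0, 2.0])


class TestChoiceProbabilities:
    def test_equal_utilities_uniform(self):
        p = tp.UtilityParams(beta={"a": 0.3})
        probs = tp.choice_probabilities(p, [[1.0], [1.0], [1.0]])
        assert np.allclose(probs, 1 / 3)

    def test_log2_utility_gap(self):
        p = tp.UtilityParams(beta={"a": 1.0})
        probs = tp.choice_probabilities(p, [[np.log(2)], [0.0]])
        assert np.allclose(probs, [2 / 3, 1 / 3])

    @given(st.integers(0, 10_000), st.floats(-300, 300))
    @settings(max_examples=60, deadline=None)
    def test_normalised_and_translation_invariant(self, seed, shift):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(4, 3))
        p = tp.UtilityParams(beta={f"c{i}": v for i, v in enumerate(rng.normal(size=3))})
        probs = tp.choice_probabilities(p, X)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs > 0).all()
        # adding a constant utility to every alternative: append a shared column
        p2 = tp.UtilityParams(beta={**p.beta, "shift": 1.0})
        X2 = np.column_stack([X, np.full(4, shift)])
        assert np.allclose(tp.choice_probabilities(p2, X2), probs, atol=1e-9)

    def test_iia_ratio_unchanged_by_third_alternative(self):
        p = tp.UtilityParams(beta={"a": 0.8, "b": -0.5})
        base = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        edited = base.copy()
        edited[2] = [-2.0, 3.0]
        r1 = tp.choice_probabilities(p, base)
        r2 = tp.choice_probabilities(p, edited)
        assert r1[0] / r1[1] == pytest.approx(r2[0] / r2[1])


class TestMNLLoglik:
    def test_zero_beta_equals_uniform(self, dataset):
        ll, _ = mnl_loglik(np.zeros(len(dataset.columns)), dataset)
        assert ll == pytest.approx(dataset.n_tasks_total * np.log(1 / 3))

    def test_gradient_matches_central_differences(self, dataset):
        rng = np.random.default_rng(0)
        K = len(dataset.columns)
        for _ in range(3):
            beta = rng.normal(scale=0.5, size=K)
            _, grad = mnl_loglik(beta, dataset)
            num = np.zeros(K)
            h = 1e-5
            for k in range(K):
                e = np.zeros(K)
                e[k] = h
                lp, _ = mnl_loglik(beta + e, dataset)
                lm, _ = mnl_loglik(beta - e, dataset)
                num[k] = (lp - lm) / (2 * h)
            assert np.max(np.abs(grad - num)) < 1e-6

    def test_duplicating_respondents_doubles_ll(self, small_dataset):
        df2 = small_dataset.df.copy()
        df2["respondent_id"] = df2["respondent_id"] + 10_000
        double = tp.ChoiceDataset(
            df=pd.concat([small_dataset.df, df2], ignore_index=True),
            columns=small_dataset.columns,
        )
        beta = np.random.default_rng(1).normal(scale=0.3, size=len(small_dataset.columns))
        ll1, g1 = mnl_loglik(beta, small_dataset)
        ll2, g2 = mnl_loglik(beta, double)
        assert ll2 == pytest.approx(2 * ll1)
        assert np.allclose(g2, 2 * g1)

    def test_hessian_negative_semidefinite(self, small_dataset):
        from tourpref.choice_models import _mnl_hessian

        X, _, _ = small_dataset.arrays()
        rng = np.random.default_rng(2)
        for _ in range(5):
            H = _mnl_hessian(rng.normal(scale=1.0, size=X.shape[2]), X)
            assert np.linalg.eigvalsh(H).max() < 1e-8


class TestFitMNL:
    def test_matches_grid_search_on_one_parameter(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2, 1))
        beta_true = np.array([0.8])
        U = X @ beta_true + rng.gumbel(size=(40, 2))
        chosen = U.argmax(axis=1)
        ds = make_tiny_dataset(X, chosen, ["a"])
        fit = tp.fit_mnl(ds)
        grid = np.linspace(-3, 3, 6001)
        lls = [mnl_loglik(np.array([b]), ds)[0] for b in grid]
        assert fit.estimates[0] == pytest.approx(grid[int(np.argmax(lls))], abs=2e-3)

    def test_matches_statsmodels_conditional_logit(self, small_dataset):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        df = small_dataset.df.copy()
        groups = df["respondent_id"].astype(str) + "_" + df["task_id"].astype(str)
        model = ConditionalLogit(
            df["chosen"].to_numpy(), df[small_dataset.columns].to_numpy(), groups=groups.to_numpy()
        )
        ref = model.fit(disp=False)
        ours = tp.fit_mnl(small_dataset)
        # statsmodels' default optimiser stops at a looser gradient tolerance
        assert np.allclose(ours.estimates, ref.params, atol=5e-4)
        assert np.allclose(ours.std_errors, ref.bse, atol=1e-3)

    def test_vcov_symmetric_psd_and_gradient_small(self, mnl_result):
        assert mnl_result.converged
        assert mnl_result.gradient_norm < 1e-6 or mnl_result.n_iterations > 0
        v = mnl_result.vcov
        assert np.allclose(v, v.T)
        assert np.linalg.eigvalsh(v).min() > -1e-12

    def test_never_chosen_alternative_with_constant_flagged(self):
        rng = np.random.default_rng(5)
        T = 30
        X = np.zeros((T, 2, 2))
        X[:, 0, 0] = rng.normal(size=T)
        X[:, 1, 1] = 1.0  # dedicated constant on an alternative never chosen
        chosen = np.zeros(T, dtype=int)
        ds = make_tiny_dataset(X, chosen, ["a", "never_const"])
        fit = tp.fit_mnl(ds, max_iter=200)
        assert not fit.converged or fit.metadata.get("divergence_suspected")

    def test_collinear_columns_named(self, small_dataset):
        df = small_dataset.df.copy()
        df["dup"] = df[small_dataset.columns[0]]
        ds = tp.ChoiceDataset(df=df, columns=small_dataset.columns + ["dup"])
        with pytest.raises(CollinearityError) as err:
            tp.fit_mnl(ds)
        assert "dup" in err.value.columns

    def test_effects_coded_level_utilities_sum_to_zero(self, mnl_result, attributes):
        levels = tp.implied_level_utilities(mnl_result, attributes)
        for _, grp in levels[levels.attribute != "opt_out"].groupby("attribute"):
            assert grp.utility.sum() == pytest.approx(0.0, abs=1e-12)


class TestHalton:
    def test_base2_prefix(self):
        assert np.allclose(tp.halton_sequence(2, 4), [0.5, 0.25, 0.75, 0.125])

    def test_drop_shifts_sequence(self):
        full = tp.halton_sequence(3, 10)
        assert np.allclose(tp.halton_sequence(3, 7, drop=3), full[3:])

    def test_values_in_open_unit_interval(self):
        for base in (2, 3, 5, 7):
            v = tp.halton_sequence(base, 500)
            assert (v > 0).all() and (v < 1).all()

    def test_nonprime_base_rejected(self):
        with pytest.raises(ValueError):
            tp.halton_sequence(4, 10)

    def test_lower_discrepancy_than_pseudorandom(self):
        from scipy.stats import qmc

        h = tp.halton_sequence(2, 500).reshape(-1, 1)
        dh = qmc.discrepancy(h, method="L2-star")
        dr = [
            qmc.discrepancy(np.random.default_rng(s).random((500, 1)), method="L2-star")
            for s in range(20)
        ]
        assert dh < np.median(dr)

    def test_normal_draws_shape_and_moments(self):
        z = halton_normal_draws(3, 2000)
        assert z.shape == (2000, 3)
        assert np.abs(z.mean(axis=0)).max() < 0.05


class TestFitMMNL:
    def test_sigma_zero_collapses_to_mnl_exactly(self, small_dataset):
        mnl = tp.fit_mnl(small_dataset)
        params = tp.UtilityParams(beta=mnl.beta, sigma={k: 0.0 for k in mnl.beta})
        sll = mmnl_simulated_loglik(params, small_dataset, n_draws=25)
        assert sll == pytest.approx(mnl.loglik, abs=1e-9)

    def test_deterministic_given_draw_settings(self, small_dataset):
        f1 = tp.fit_mmnl(small_dataset, n_draws=50, max_iter=5, compute_se=False)
        f2 = tp.fit_mmnl(small_dataset, n_draws=50, max_iter=5, compute_se=False)
        assert np.array_equal(f1.estimates, f2.estimates)

    def test_fitted_ll_dominates_mnl_on_heterogeneous_data(self, design):
        gen = tp.default_generator_config(seed=21, design=design, heterogeneous=True,
                                          n_respondents=120)
        ds = tp.generate_choices(gen)
        mnl = tp.fit_mnl(ds)
        mmnl = tp.fit_mmnl(ds, n_draws=100, compute_se=False)
        assert mmnl.loglik >= mnl.loglik - 1e-6

    def test_sds_reported_nonnegative(self, small_dataset):
        fit = tp.fit_mmnl(small_dataset, n_draws=50, max_iter=30, compute_se=False)
        assert all(v >= 0 for v in fit.sigma.values())


class TestChoiceDatasetInvariants:
    def test_two_chosen_rows_rejected(self, small_dataset):
        df = small_dataset.df.copy()
        df.loc[df.index[:3], "chosen"] = 1
        with pytest.raises(ValueError):
            tp.ChoiceDataset(df=df, columns=small_dataset.columns)

    def test_nonzero_opt_out_attributes_rejected(self, small_dataset):
        df = small_dataset.df.copy()
        mask = df["opt_out"] == 1
        df.loc[mask, small_dataset.columns[0]] = 1.0
        with pytest.raises(ValueError):
            tp.ChoiceDataset(df=df, columns=small_dataset.columns)
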