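"""Design construction: factorial enumeration, effects coding, D-error, search."""

import numpy as np
import pytest

import tourpref as tp
from tourpref.experimental_design import (
    SingularDesignError,
    code_profiles,
    coded_design_array,
    design_columns,
)


def brute_force_d_error(design: tp.ChoiceDesign, priors: np.ndarray) -> float:
    """Independent oracle: sum P_j (x_j - xbar)(x_j - xbar)' over tasks, loops only."""
    X = coded_design_array(design)
    T, J, K = X.shape
    info = np.zeros((K, K))
    for t in range(T):
        u = [float(X[t, j] @ priors) for j in range(J)]
        m = max(u)
        e = [np.exp(v - m) for v in u]
        P = [v / sum(e) for v in e]
        xbar = sum(P[j] * X[t, j] for j in range(J))
        for j in range(J):
            d = X[t, j] - xbar
            info += P[j] * np.outer(d, d)
    det = np.linalg.det(info)
    return float(det ** (-1.0 / K)) if det > 0 else float("inf")


class TestEnumeration:
    def test_single_attribute_identity(self):
        a = tp.AttributeSpec(name="a", levels=("x", "y", "z"))
        assert tp.enumerate_full_factorial([a]).tolist() == [[0], [1], [2]]

    def test_study_instrument_has_432_profiles(self, attributes):
        ff = tp.enumerate_full_factorial(attributes)
        assert ff.shape == (432, 5)
        assert len(np.unique(ff, axis=0)) == 432

    def test_two_binary_attributes(self):
        attrs = [
            tp.AttributeSpec(name="a", levels=("0", "1")),
            tp.AttributeSpec(name="b", levels=("0", "1")),
        ]
        ff = tp.enumerate_full_factorial(attrs)
        assert ff.shape == (4, 2) and len(np.unique(ff, axis=0)) == 4

    def test_empty_attribute_list_rejected(self):
        with pytest.raises(ValueError):
            tp.enumerate_full_factorial([])


class TestEffectsCoding:
    def test_three_level_conventions(self):
        a = tp.AttributeSpec(name="a", levels=("l1", "l2", "l3"))
        assert tp.effects_code([0], [a]).tolist() == [1.0, 0.0]
        assert tp.effects_code([2], [a]).tolist() == [-1.0, -1.0]

    def test_continuous_money_level_carries_gmd_value(self):
        money = tp.AttributeSpec(
            name="money",
            levels=("No money", "500 dalasi", "1000 dalasi", "2000 dalasi"),
            coding="continuous",
            numeric_values=(0, 500, 1000, 2000),
        )
        assert tp.effects_code([3], [money]).tolist() == [2000.0]

    def test_level_out_of_range(self):
        a = tp.AttributeSpec(name="a", levels=("x", "y"))
        with pytest.raises(ValueError):
            tp.effects_code([2], [a])

    def test_full_factorial_columns_balance_to_zero(self, attributes):
        coded = code_profiles(tp.enumerate_full_factorial(attributes), attributes)
        assert np.allclose(coded.sum(axis=0), 0.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            tp.AttributeSpec(name="a", levels=("only",))
        with pytest.raises(ValueError):
            tp.AttributeSpec(name="a", levels=("x", "x"))
        with pytest.raises(ValueError):
            tp.AttributeSpec(name="a", levels=("x", "y"), coding="continuous")


class TestDError:
    def test_identical_profiles_are_singular(self, toy_binary_attribute):
        profiles = np.zeros((2, 2, 1), dtype=int)  # both alternatives identical
        d = tp.ChoiceDesign([toy_binary_attribute], profiles, has_opt_out=False)
        assert tp.d_error(d, [0.0]) == float("inf")

    def test_matches_brute_force_oracle(self, toy_binary_attribute):
        profiles = np.array([[[0], [1]], [[1], [0]]])
        d = tp.ChoiceDesign([toy_binary_attribute], profiles, has_opt_out=False)
        assert tp.d_error(d, [0.0]) == pytest.approx(brute_force_d_error(d, np.zeros(1)))

    def test_matches_brute_force_on_study_design(self, design, generator):
        priors = generator.true_params.beta_vector(design.columns())
        assert tp.d_error(design, priors) == pytest.approx(
            brute_force_d_error(design, priors), rel=1e-10
        )

    def test_zero_priors_equal_utility_neutral(self, design):
        K = len(design.columns())
        assert tp.d_error(design, np.zeros(K)) == pytest.approx(
            tp.d_error(design, 0 * np.ones(K))
        )

    def test_invariant_to_task_order(self, design, generator):
        priors = generator.true_params.beta_vector(design.columns())
        shuffled = tp.ChoiceDesign(
            design.attributes, design.profiles[::-1].copy(), has_opt_out=True
        )
        assert tp.d_error(shuffled, priors) == pytest.approx(tp.d_error(design, priors))

    def test_prior_length_checked(self, design):
        with pytest.raises(ValueError):
            tp.d_error(design, [0.0, 1.0])


class TestSearch:
    def test_exhaustive_minimum_on_toy_space(self, toy_binary_attribute):
        # 2 tasks x 2 alternatives over 2 candidate profiles: 16 designs total
        best = float("inf")
        for bits in range(16):
            ix = np.array([(bits >> k) & 1 for k in range(4)]).reshape(2, 2)
            d = tp.ChoiceDesign([toy_binary_attribute], ix[:, :, None], has_opt_out=False)
            best = min(best, tp.d_error(d, [0.2]))
        found = tp.search_efficient_design(
            [toy_binary_attribute], [0.2], n_tasks=2, n_alternatives=2,
            seed=0, n_restarts=4, has_opt_out=False,
        )
        assert tp.d_error(found, [0.2]) == pytest.approx(best)

    def test_study_shape_design(self, design):
        assert design.n_tasks == 8
        assert design.n_profile_alternatives == 2
        assert design.has_opt_out
        assert np.isfinite(design.metadata["d_error"])

    def test_deterministic_given_seed(self, toy_binary_attribute):
        attrs = [toy_binary_attribute, tp.AttributeSpec(name="b", levels=("p", "q", "r"))]
        kw = dict(n_tasks=3, n_alternatives=2, n_restarts=2, has_opt_out=True)
        d1 = tp.search_efficient_design(attrs, np.zeros(4), seed=11, **kw)
        d2 = tp.search_efficient_design(attrs, np.zeros(4), seed=11, **kw)
        assert np.array_equal(d1.profiles, d2.profiles)

    def test_search_never_worse_than_random_start(self, toy_binary_attribute):
        attrs = [toy_binary_attribute, tp.AttributeSpec(name="b", levels=("p", "q", "r"))]
        priors = np.array([0.1, -0.2, 0.3, 0.0])
        for seed in (1, 2, 3):
            found = tp.search_efficient_design(
                attrs, priors, n_tasks=3, n_alternatives=2, seed=seed, n_restarts=1
            )
            rng = np.random.default_rng(seed)
            ff = tp.enumerate_full_factorial(attrs)
            start_ix = rng.integers(0, len(ff), size=(3, 2))
            start = tp.ChoiceDesign(attrs, ff[start_ix], has_opt_out=True)
            assert tp.d_error(found, priors) <= tp.d_error(start, priors) + 1e-12

    def test_all_singular_space_raises(self):
        # a single 2-level attribute with an opt-out column but only one task
        # slot per alternative cannot identify 2 params from 1 contrast if the
        # candidate set is restricted to a single profile
        a = tp.AttributeSpec(name="a", levels=("x", "y"))
        with pytest.raises(SingularDesignError):
            # n_alternatives=1 with opt-out: opt-out constant and the level
            # contrast are confounded task-by-task only when profiles repeat;
            # a 1-task design cannot identify both parameters
            tp.search_efficient_design([a], np.zeros(2), n_tasks=1, n_alternatives=1, seed=0)


class TestDesignExport:
    def test_json_round_trip(self, design, tmp_path):
        p = tmp_path / "design.json"
        design.to_json(p)
        back = tp.ChoiceDesign.from_json(p)
        assert np.array_equal(back.profiles, design.profiles)
        assert back.columns() == design.columns()

    def test_questionnaire_layout(self, design):
        q = design.questionnaire()
        # 8 tasks x (2 profiles + neither)
        assert len(q) == 24
        assert (q["alternative"] == "Neither").sum() == 8
        assert set(q.columns) >= {"task", "alternative", "condom_use", "money"}

    def test_columns_catalogue(self, attributes):
        cols = design_columns(attributes)
        assert cols[-1] == "opt_out"
        assert len(cols) == 13  # (3-1)+(4-1)+(3-1)+(4-1)+(3-1) + opt-out
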