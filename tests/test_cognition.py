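import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from traplinesim.cognition import (
    BeeParams,
    NoAllowedDestination,
    WorkingMemory,
    build_discovery_matrix,
    choice_probabilities,
    choose_next,
    perceived_value,
    q_init,
    q_update,
    q_table_to_frame,
)
from traplinesim.environment import ConfigurationError

from conftest import make_env


class TestDiscoveryMatrix:
    def test_rows_sum_to_one_on_random_environments(self):
        from traplinesim.environment import generate_uniform

        for seed in range(5):
            env = generate_uniform(20, 300.0, rng_seed=seed)
            pd_mat = build_discovery_matrix(env)
            assert np.allclose(pd_mat.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(np.diag(pd_mat) == 0.0)

    def test_equal_distances_split_evenly(self):
        env = make_env([(10.0, 0.0), (-10.0, 0.0)], arena_side=100.0)
        pd_mat = build_discovery_matrix(env)
        # from the nest, both sites are 10 m away
        assert pd_mat[0, 1] == pytest.approx(0.5)
        assert pd_mat[0, 2] == pytest.approx(0.5)

    def test_inverse_square_weighting(self):
        # destinations at r and 2r from the nest -> 4/5 and 1/5
        env = make_env([(10.0, 0.0), (20.0, 0.0)], arena_side=100.0)
        pd_mat = build_discovery_matrix(env)
        assert pd_mat[0, 1] == pytest.approx(4.0 / 5.0)
        assert pd_mat[0, 2] == pytest.approx(1.0 / 5.0)

    def test_coincident_locations_rejected(self):
        env = make_env([(5.0, 5.0), (5.0, 5.0)], arena_side=100.0)
        with pytest.raises(ConfigurationError, match="coincident"):
            build_discovery_matrix(env)

    def test_closer_destination_more_probable(self):
        env = make_env([(10.0, 0.0), (15.0, 0.0), (40.0, 0.0)], arena_side=100.0)
        pd_mat = build_discovery_matrix(env)
        assert pd_mat[0, 1] > pd_mat[0, 2] > pd_mat[0, 3]


class TestValuesAndUpdates:
    @pytest.mark.parametrize(
        "nectar,p,expected", [(0.0, 0.7, 0.0), (20.0, 1.0, 20.0), (10.0, 0.2, 2.0)]
    )
    def test_perceived_value(self, nectar, p, expected):
        assert perceived_value(nectar, p) == pytest.approx(expected)

    def test_perceived_value_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            perceived_value(-1.0, 0.5)
        with pytest.raises(ValueError):
            perceived_value(1.0, 1.5)

    def test_q_init_formula(self):
        pd_mat = np.array([[0.0, 0.25, 0.75], [0.4, 0.0, 0.6], [0.5, 0.5, 0.0]])
        q0 = q_init(pd_mat, n_max=20.0)
        assert q0[0, 1] == pytest.approx(2.5)
        assert np.all(np.diag(q0) == 0.0)
        assert np.allclose(q0.sum(axis=1), 10.0)  # n_max / 2 per row

    @pytest.mark.parametrize(
        "alpha,q_prev,v,expected", [(0.0, 4.0, 8.0, 4.0), (1.0, 4.0, 8.0, 8.0), (0.5, 4.0, 8.0, 6.0)]
    )
    def test_q_update(self, alpha, q_prev, v, expected):
        assert q_update(q_prev, v, alpha) == pytest.approx(expected)

    def test_q_update_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            q_update(1.0, 1.0, 1.5)

    @given(
        q=st.floats(0.0, 20.0),
        v=st.floats(0.0, 20.0),
        alpha=st.floats(0.0, 1.0),
    )
    def test_update_stays_in_value_range(self, q, v, alpha):
        assert 0.0 <= q_update(q, v, alpha) <= 20.0


class TestChoice:
    def test_beta_zero_is_uniform(self):
        probs = choice_probabilities(np.array([0.1, 5.0, 2.0, 0.4]), 0.0,
                                     np.array([True, True, True, True]))
        assert np.allclose(probs, 0.25)

    def test_equal_values_are_uniform_any_beta(self):
        probs = choice_probabilities(np.full(5, 3.3), 17.0, np.ones(5, bool))
        assert np.allclose(probs, 0.2)

    def test_large_beta_approaches_argmax(self):
        q = np.array([0.5, 1.0, 0.8])
        beta = 200.0
        probs = choice_probabilities(q, beta, np.ones(3, bool))
        # direct evaluation of the softmax formula as an oracle
        ref = np.exp(beta * q) / np.exp(beta * q).sum()
        assert np.allclose(probs, ref, atol=1e-12)
        assert probs[1] > 0.999

    def test_excluded_get_zero_and_rest_renormalize(self):
        probs = choice_probabilities(np.array([1.0, 2.0, 3.0]), 1.0,
                                     np.array([True, False, True]))
        assert probs[1] == 0.0
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_allowed_set_signalled(self):
        with pytest.raises(NoAllowedDestination):
            choice_probabilities(np.array([1.0]), 1.0, np.array([False]))

    def test_numerical_stability_at_large_beta_q(self):
        q = np.array([100.0, 99.0])  # beta * q up to 1e4
        probs = choice_probabilities(q, 100.0, np.ones(2, bool))
        assert np.isfinite(probs).all()
        assert probs.sum() == pytest.approx(1.0)

    @given(
        q=st.lists(st.floats(0.0, 20.0), min_size=2, max_size=10),
        beta=st.floats(0.0, 100.0),
    )
    @settings(max_examples=50)
    def test_probabilities_sum_to_one(self, q, beta):
        probs = choice_probabilities(np.array(q), beta, np.ones(len(q), bool))
        assert abs(probs.sum() - 1.0) < 1e-12


class TestChooseNext:
    def test_degenerate_distribution(self):
        rng = np.random.default_rng(0)
        probs = np.array([0.0, 1.0, 0.0])
        assert all(choose_next(probs, rng) == 1 for _ in range(20))

    def test_reproducible_under_rng_state(self):
        probs = np.full(4, 0.25)
        a = choose_next(probs, np.random.default_rng(5))
        b = choose_next(probs, np.random.default_rng(5))
        assert a == b

    def test_uniform_frequencies(self):
        # binomial oracle: each frequency within 5 SE of 1/4
        rng = np.random.default_rng(123)
        n = 100_000
        draws = np.array([choose_next(np.full(4, 0.25), rng) for _ in range(n)])
        se = np.sqrt(0.25 * 0.75 / n)
        freqs = np.bincount(draws, minlength=4) / n
        assert np.all(np.abs(freqs - 0.25) < 5 * se)

    def test_malformed_distribution_rejected(self):
        with pytest.raises(ValueError):
            choose_next(np.array([0.5, 0.2]), np.random.default_rng(0))


class TestWorkingMemory:
    def test_half_open_exclusion_window(self):
        wm = WorkingMemory(span=30.0)
        wm.record(3, time=100.0)
        assert wm.is_excluded(3, 100.0)
        assert wm.is_excluded(3, 129.9)
        assert not wm.is_excluded(3, 130.0)

    def test_zero_span_never_excludes(self):
        wm = WorkingMemory(span=0.0)
        wm.record(1, time=50.0)
        assert not wm.is_excluded(1, 50.0)
        assert not wm.excluded_mask(50.0, 4).any()

    def test_mask_matches_scalar_queries(self):
        wm = WorkingMemory(span=10.0)
        wm.record(0, 0.0)
        wm.record(2, 5.0)
        mask = wm.excluded_mask(8.0, 4)
        assert mask.tolist() == [True, False, True, False]


def test_bee_params_validation():
    with pytest.raises(ConfigurationError):
        BeeParams(alpha=1.5)
    with pytest.raises(ConfigurationError):
        BeeParams(beta=-1.0)
    with pytest.raises(ConfigurationError):
        BeeParams(speed=0.0)


def test_q_table_export_long_form():
    q = np.arange(9, dtype=float).reshape(3, 3)
    df = q_table_to_frame(q)
    assert len(df) == 9
    assert df.iloc[0]["origin"] == "nest"
    row = df[(df.origin == "0") & (df.destination == "1")]
    assert float(row["q_value"].iloc[0]) == q[1, 2]
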