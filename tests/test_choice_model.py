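"""Tests of the utility family: hand-arithmetic oracles, algebraic
identities, monotonicity, variant behavior, and simulation reproducibility."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from harmalloc.choice_model import (
    SubjectParams,
    VARIANTS,
    choice_prob,
    design_arrays,
    log_likelihood,
    logits,
    mean_choice_prob,
    simulate_choices,
    utility_components,
)
from harmalloc.task_design import TrialSpec, enumerate_valid_pairs

valid_triples = enumerate_valid_pairs()


def params_strategy():
    return st.builds(
        SubjectParams,
        alpha=st.floats(0.0, 1.0),
        phi=st.floats(-50, 50),
        tau=st.floats(0.01, 5.0),
    )


trial_strategy = st.sampled_from(valid_triples).map(
    lambda t: TrialSpec(c_one=t[0], c_group=t[1], n_group=t[2])
)


class TestUtilityOracles:
    def test_hand_arithmetic_example(self):
        # dtotal = 40*3-100 = 20; dsingle = 100-40 = 60
        # dU = 0.05*20 - 0.95*(60-10) = 1 - 47.5 = -46.5
        uc = utility_components(TrialSpec(100, 40, 3),
                                SubjectParams(0.95, -10.0, 0.1))
        assert uc.delta_total == 20
        assert uc.delta_single == 60
        assert uc.delta_u == pytest.approx(-46.5, abs=1e-12)

    def test_softmax_hand_value(self):
        p = choice_prob(TrialSpec(100, 40, 3), SubjectParams(0.95, -10.0, 0.1))
        assert p == pytest.approx(1.0 / (1.0 + np.exp(4.65)), rel=1e-12)

    def test_utilitarian_boundary(self):
        # c_one = c_group * n  =>  dtotal = 0, so alpha=0 gives dU = 0
        uc = utility_components(TrialSpec(120, 40, 3), SubjectParams(0.0, 7.0, 1.0))
        assert uc.delta_u == 0.0

    def test_maximin_limit(self):
        for (c1, cg, n) in valid_triples[::17]:
            uc = utility_components(TrialSpec(c1, cg, n),
                                    SubjectParams(1.0, 0.0, 1.0))
            assert uc.delta_u == pytest.approx(-(c1 - cg))
            assert uc.delta_u <= 0

    @given(trial=trial_strategy, params=params_strategy())
    @settings(max_examples=200, deadline=None)
    def test_identity_du_equals_utility_difference(self, trial, params):
        uc = utility_components(trial, params)
        assert uc.delta_u == pytest.approx(uc.u_one - uc.u_group, abs=1e-9)

    @given(trial=trial_strategy, params=params_strategy())
    @settings(max_examples=100, deadline=None)
    def test_du_slope_in_c_one_is_minus_one(self, trial, params):
        # d(dU)/dC_one = -1 exactly, independent of alpha
        arrays = {
            "c_one": np.array([trial.c_one, trial.c_one + 1.0]),
            "c_group": np.full(2, trial.c_group),
            "n_group": np.full(2, float(trial.n_group)),
            "default_sign": np.zeros(2),
        }
        lt = logits(arrays, {"alpha": params.alpha, "phi": params.phi,
                             "tau": 1.0, "kappa": 0.0})
        assert lt[1] - lt[0] == pytest.approx(-1.0, abs=1e-9)


class TestChoiceProb:
    def test_half_at_zero_du(self):
        # alpha=0 and dtotal=0 make dU vanish for any tau
        t = TrialSpec(120, 40, 3)
        for tau in (0.01, 1.0, 50.0):
            assert choice_prob(t, SubjectParams(0.0, 0.0, tau)) == 0.5

    def test_deterministic_limit(self):
        p = choice_prob(TrialSpec(100, 40, 3), SubjectParams(0.95, -10.0, 1e6))
        assert p < 1e-12  # dU < 0, huge tau => group almost surely

    def test_monotone_decreasing_in_c_one(self):
        params = SubjectParams(0.6, -5.0, 0.3)
        probs = [
            choice_prob(TrialSpec(c1, 40.0, 3), params)
            for c1 in (40.0, 60.0, 90.0, 120.0)
        ]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_alpha_one_threshold_property(self):
        # under pure maximin, "one" is preferred iff dsingle < -phi
        phi = -55.0
        params = SubjectParams(1.0, phi, 0.5)
        below = TrialSpec(80.0, 30.0, 3)   # dsingle = 50 < 55
        above = TrialSpec(90.0, 30.0, 3)   # dsingle = 60 > 55
        assert choice_prob(below, params) > 0.5
        assert choice_prob(above, params) < 0.5

    def test_ratio_and_constant_phi_coincide(self):
        # phi_ratio = 1 reproduces the constant model at phi_const = 0
        arr = {
            "c_one": np.array([100.0, 60.0]),
            "c_group": np.array([40.0, 30.0]),
            "n_group": np.array([3.0, 4.0]),
            "default_sign": np.zeros(2),
        }
        const = logits(arr, {"alpha": 0.7, "phi": 0.0, "tau": 0.2, "kappa": 0.0},
                       ratio_phi=False)
        ratio = logits(arr, {"alpha": 0.7, "phi": 1.0, "tau": 0.2, "kappa": 0.0},
                       ratio_phi=True)
        np.testing.assert_allclose(const, ratio, atol=1e-12)


class TestLikelihoodAndSimulation:
    def test_loglik_of_indifferent_trial(self):
        df = pd.DataFrame({
            "c_one": [120.0], "c_group": [40.0], "n_group": [3],
            "default_cond": ["none"], "chose_one": [1],
        })
        total, pointwise = log_likelihood(df, SubjectParams(0.0, 0.0, 1.0))
        assert total == pytest.approx(np.log(0.5))
        assert pointwise.shape == (1,)

    def test_tau_small_limit_is_coin_flips(self, design_150):
        df = simulate_choices(design_150, SubjectParams(0.5, 0.0, 1e-9), seed=0)
        total, _ = log_likelihood(df, SubjectParams(0.5, 0.0, 1e-9))
        assert total == pytest.approx(150 * np.log(0.5), rel=1e-6)

    def test_independent_recomputation_matches(self, design_150, rng):
        """Second code path: per-trial scalar probabilities via choice_prob."""
        params = SubjectParams(0.9, -8.0, 0.12)
        data = simulate_choices(design_150, params, seed=5)
        _, pointwise = log_likelihood(data, params)
        from harmalloc.task_design import design_to_trials

        for k in rng.choice(len(data), size=25, replace=False):
            row = data.iloc[int(k)]
            t = TrialSpec(row.c_one, row.c_group, int(row.n_group),
                          row.default_cond, int(row.trial_index))
            p_one = choice_prob(t, params)
            expected = np.log(p_one if row.chose_one == 1 else 1.0 - p_one)
            assert pointwise[int(k)] == pytest.approx(expected, abs=1e-12)

    def test_missing_choices_error(self, design_150):
        df = design_150.copy()
        with pytest.raises(ValueError):
            log_likelihood(df, SubjectParams(0.5, 0.0, 1.0))

    def test_simulation_reproducible_and_seed_sensitive(self, design_150):
        p = SubjectParams(0.95, -10.0, 0.1)
        a = simulate_choices(design_150, p, seed=11)
        b = simulate_choices(design_150, p, seed=11)
        c = simulate_choices(design_150, p, seed=12)
        assert a.equals(b)
        assert not a["chose_one"].equals(c["chose_one"])

    def test_deterministic_regime_all_group(self, design_150):
        # tau huge and dU < 0 on every trial (phi large positive) => all group
        df = simulate_choices(design_150, SubjectParams(0.95, 100.0, 50.0),
                              seed=3)
        assert (df["chose_one"] == 0).all()

    def test_choice_frequency_matches_analytic_mean(self, design_150):
        params = SubjectParams(0.95, -10.0, 0.1)
        target = mean_choice_prob(design_150, params)
        reps = [
            simulate_choices(design_150, params, seed=s)["chose_one"].mean()
            for s in range(10)
        ]
        # 1500 Bernoulli draws: 4 sigma margin on the mean
        se = np.sqrt(target * (1 - target) / (150 * 10))
        assert abs(np.mean(reps) - target) < 4 * se
        assert target < 0.5  # Rawlsian-dominant regime prefers the group
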