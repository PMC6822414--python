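import math

import numpy as np
import pandas as pd
import pytest

from capdce.estimate import (
    compute_fit_stats,
    fit_mmnl,
    fit_mnl,
    fit_stats,
    mmnl_simulated_loglik,
    mnl_loglik,
)
from capdce.simulate import ChoiceDataset, DataError, SimulationConfig, simulate_choices
from tests.conftest import PILOT_BETA


def toy_dataset():
    """2 respondents x 1 task x 2 alternatives, K = 2."""
    table = pd.DataFrame({
        "respondent_id": [1, 1, 2, 2],
        "task_id": [1, 1, 1, 1],
        "alt_id": [1, 2, 1, 2],
        "chosen": [1, 0, 0, 1],
        "is_optout": [0, 0, 0, 0],
        "x1": [1.0, 0.0, 1.0, 0.0],
        "x2": [0.0, 2.0, 1.0, 2.0],
    })
    return ChoiceDataset(table=table, param_names=("x1", "x2"))


class TestLogLikelihood:
    def test_equal_shares_value(self, pilot_data):
        # beta = 0, 248 observations x 3 alternatives
        assert mnl_loglik(np.zeros(6), pilot_data) == pytest.approx(248 * math.log(1 / 3), rel=1e-12)
        assert 248 * math.log(1 / 3) == pytest.approx(-272.456, abs=1e-3)

    def test_matches_brute_force_oracle(self):
        # independent oracle: log softmax terms written out row by row
        data = toy_dataset()
        beta = np.array([0.5, -0.3])
        v11, v12 = 1 * 0.5 + 0 * -0.3, 0 * 0.5 + 2 * -0.3
        v21, v22 = 1 * 0.5 + 1 * -0.3, 0 * 0.5 + 2 * -0.3
        expected = (v11 - math.log(math.exp(v11) + math.exp(v12))
                    + v22 - math.log(math.exp(v21) + math.exp(v22)))
        assert mnl_loglik(beta, data) == pytest.approx(expected, rel=1e-12)

    def test_dominant_choice_ll_approaches_zero(self):
        data = toy_dataset()
        t = data.table.copy()
        t["chosen"] = [1, 0, 1, 0]
        data = ChoiceDataset(table=t, param_names=data.param_names)
        ll = mnl_loglik(np.array([50.0, 0.0]), data)
        assert -1e-10 < ll <= 0

    def test_shift_invariance(self, pilot_data):
        # adding a constant to all utilities within each task leaves LL unchanged
        beta = PILOT_BETA.copy()
        shifted = pilot_data.table.copy()
        shifted["const"] = 1.0
        data2 = ChoiceDataset(table=shifted, param_names=pilot_data.param_names + ("const",))
        ll_a = mnl_loglik(beta, pilot_data)
        ll_b = mnl_loglik(np.r_[beta, 123.456], data2)
        assert ll_b == pytest.approx(ll_a, rel=1e-12)

    def test_beta_length_checked(self, pilot_data):
        with pytest.raises(DataError, match="length"):
            mnl_loglik(np.zeros(3), pilot_data)


class TestFitMNL:
    def test_parameter_recovery_within_3_robust_se(self, big_data):
        res = fit_mnl(big_data)
        assert res.converged
        z = np.abs(res.beta_hat - PILOT_BETA) / res.se_robust
        assert np.all(z < 3), z

    def test_start_point_invariance(self, big_data):
        r1 = fit_mnl(big_data)
        r2 = fit_mnl(big_data, start=np.array([0.5, -1.0, 0.002, 0.3, -0.4, 1.5]))
        assert np.max(np.abs(r1.beta_hat - r2.beta_hat)) < 1e-6

    def test_gradient_norm_below_tol(self, pilot_data, big_data):
        for data in (pilot_data, big_data):
            res = fit_mnl(data)
            assert res.converged and res.grad_norm <= 1e-8

    def test_ll_final_beats_start(self, pilot_data):
        res = fit_mnl(pilot_data)
        assert res.ll_final >= mnl_loglik(np.zeros(6), pilot_data)
        assert res.ll_final == pytest.approx(mnl_loglik(res.beta_hat, pilot_data), rel=1e-10)

    def test_covariances_symmetric_nonnegative_diagonal(self, pilot_data):
        res = fit_mnl(pilot_data)
        for cov in (res.cov_classical, res.cov_robust):
            np.testing.assert_allclose(cov, cov.T, atol=1e-12)
            assert np.all(np.diag(cov) >= 0)

    def test_observation_accounting(self, pilot_data):
        res = fit_mnl(pilot_data)
        assert res.n_obs == 248
        assert res.n_respondents == 31

    def test_constant_attribute_flags_nonconvergence(self, pilot_design):
        cfg = SimulationConfig(beta_true=PILOT_BETA, n_respondents=20, seed=3)
        data = simulate_choices(pilot_design, cfg)
        t = data.table.copy()
        t["dead"] = 0.0  # no contrast anywhere -> not identified
        data2 = ChoiceDataset(table=t, param_names=data.param_names + ("dead",))
        res = fit_mnl(data2)
        assert not res.converged

    def test_sandwich_equals_classical_with_one_task_per_respondent(self, pilot_design):
        # one observation per cluster: meat = observed information asymptotically;
        # here we check the exact degeneracy cov_robust = A^-1 (sum g g') A^-1
        # computed with per-observation clustering equals respondent clustering
        cfg = SimulationConfig(beta_true=PILOT_BETA, n_respondents=300, seed=9)
        data = simulate_choices(pilot_design, cfg)
        one_task = data.table[data.table["task_id"] == data.table["task_id"].min()]
        d1 = ChoiceDataset(table=one_task.copy(), param_names=data.param_names)
        r_clustered = fit_mnl(d1, cluster_by_respondent=True)
        r_obs = fit_mnl(d1, cluster_by_respondent=False)
        np.testing.assert_allclose(r_clustered.cov_robust, r_obs.cov_robust, rtol=1e-8)

    def test_forced_choice_drops_optout(self, pilot_data):
        res = fit_mnl(pilot_data, include_optout=False)
        assert "optout" not in res.param_names
        assert res.k == 5
        chose_oo = ((pilot_data.table["is_optout"] == 1)
                    & (pilot_data.table["chosen"] == 1)).sum()
        assert res.n_dropped_tasks == int(chose_oo)
        assert res.n_obs == 248 - int(chose_oo)

    def test_forced_choice_equals_full_fit_on_same_rows(self, pilot_design):
        # when the opt-out is never chosen, forced choice keeps every task;
        # refit the full model on the opt-out-free rows for comparison
        beta = PILOT_BETA.copy()
        beta[-1] = -30.0  # opt-out essentially never chosen
        cfg = SimulationConfig(beta_true=beta, n_respondents=100, seed=21)
        data = simulate_choices(pilot_design, cfg)
        res_fc = fit_mnl(data, include_optout=False)
        assert res_fc.n_dropped_tasks == 0
        reduced, _ = data.drop_optout()
        res_manual = fit_mnl(reduced)
        np.testing.assert_allclose(res_fc.beta_hat, res_manual.beta_hat, atol=1e-9)
        assert res_fc.ll_final == pytest.approx(res_manual.ll_final, rel=1e-12)


class TestFitStats:
    def test_printed_aic_bic(self):
        st = compute_fit_stats(ll_final=-222.5633, k=6, n_obs=248, ll_baseline=-250.6159)
        assert round(st.aic, 2) == 457.13
        assert round(st.bic, 2) == 478.21

    def test_printed_adjusted_rho2(self):
        st = compute_fit_stats(ll_final=-222.5633, k=6, n_obs=248, ll_baseline=-250.6159)
        assert round(st.adj_rho2, 2) == 0.09

    def test_zero_k_baseline_equality(self):
        st = compute_fit_stats(ll_final=-100.0, k=0, n_obs=10, ll_baseline=-100.0)
        assert st.adj_rho2 == pytest.approx(0.0)

    def test_baseline_default_is_equal_shares(self, pilot_data):
        res = fit_mnl(pilot_data)
        st = fit_stats(res)
        assert st.baseline_used == "equal_shares"
        assert st.adj_rho2 == pytest.approx(1 - (res.ll_final - 6) / res.ll_null)

    def test_user_baseline(self, pilot_data):
        res = fit_mnl(pilot_data)
        st = fit_stats(res, baseline=-250.6159)
        assert st.baseline_used == "user_supplied"

    def test_invalid_n_obs(self):
        with pytest.raises(ValueError, match="n_obs"):
            compute_fit_stats(-10.0, 2, 0, -12.0)


class TestMMNL:
    def test_zero_sds_equals_mnl_loglik_exactly(self, pilot_data):
        res = fit_mnl(pilot_data)
        ll = mnl_loglik(res.beta_hat, pilot_data)
        sim = mmnl_simulated_loglik(pilot_data, res.beta_hat,
                                    ("payment_timeliness",), [0.0], n_draws=64)
        assert sim == ll  # bitwise

    def test_seed_and_draw_determinism(self, pilot_data):
        args = (pilot_data, PILOT_BETA, ("payment_timeliness",), [0.25])
        a = mmnl_simulated_loglik(*args, n_draws=32, seed=5)
        b = mmnl_simulated_loglik(*args, n_draws=32, seed=5)
        assert a == b

    def test_pseudorandom_draws_seed_sensitivity(self, pilot_data):
        args = (pilot_data, PILOT_BETA, ("payment_timeliness",), [0.25])
        a = mmnl_simulated_loglik(*args, n_draws=32, draw_type="pseudorandom", seed=1)
        b = mmnl_simulated_loglik(*args, n_draws=32, draw_type="pseudorandom", seed=2)
        assert a != b

    def test_invalid_draw_count(self, pilot_data):
        with pytest.raises(ValueError, match="n_draws"):
            fit_mmnl(pilot_data, ("payment_timeliness",), n_draws=0)

    def test_unknown_random_name(self, pilot_data):
        with pytest.raises(DataError, match="unknown random"):
            fit_mmnl(pilot_data, ("bogus",), n_draws=8)

    def test_random_coefficient_recovery(self, pilot_design):
        # DGP: normal random coefficient (mean 0.5, sd 0.3) on timeliness
        beta = PILOT_BETA.copy()
        beta[1] = 0.5
        cfg = SimulationConfig(beta_true=beta, n_respondents=500, seed=31,
                               random_sds={"payment_timeliness": 0.3})
        data = simulate_choices(pilot_design, cfg)
        mm = fit_mmnl(data, ("payment_timeliness",), n_draws=100, seed=0, compute_se=True)
        i = mm.param_names.index("payment_timeliness")
        assert abs(mm.means[i] - 0.5) < 3 * mm.se_means[i]
        assert abs(mm.sds[0] - 0.3) < 3 * mm.se_sds[0]
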