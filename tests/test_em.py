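import numpy as np
import pytest
from scipy import optimize, stats

from adaptref.data_model import Sigma2Spec, simulate_population, validate_table
from adaptref.em import (
    EMState,
    dynamic_band_em,
    e_step,
    em_fit,
    fit_stream,
    init_state,
    m_step,
    marginal_loglik,
    predictive_normal,
    predictive_score_em,
    sema_update,
)
from adaptref.errors import DataError


def manual_state(mu, tau2, sigma2, n, ybar, y2bar):
    sigma2 = np.asarray(sigma2, dtype=float)
    I = sigma2.size
    return EMState(
        subject_ids=[f"S{k}" for k in range(I)],
        mu_hat=mu,
        tau2_hat=tau2,
        sigma2_hat=sigma2,
        mu_i_hat=np.zeros(I),
        nu_i_hat=np.zeros(I),
        rho_i_hat=np.zeros(I),
        T1=0.0,
        T2=0.0,
        T3=np.zeros(I),
        n_i=np.asarray(n, dtype=float),
        ybar_i=np.asarray(ybar, dtype=float),
        y2bar_i=np.asarray(y2bar, dtype=float),
    )


class TestEStep:
    def test_equal_precision_case(self):
        st = manual_state(0.0, 1.0, [1.0], [1], [2.0], [4.0])
        e_step(st)
        assert st.rho_i_hat[0] == pytest.approx(0.5)
        assert st.mu_i_hat[0] == pytest.approx(1.0)
        assert st.nu_i_hat[0] == pytest.approx(0.5)

    def test_data_dominated_limit(self):
        st = manual_state(0.0, 1.0, [1e-12], [100], [2.0], [4.0])
        e_step(st)
        assert st.rho_i_hat[0] == pytest.approx(1.0, abs=1e-10)
        assert st.mu_i_hat[0] == pytest.approx(2.0, abs=1e-9)

    def test_pooled_limit(self):
        st = manual_state(7.0, 1e-14, [1.0], [5], [2.0], [4.0])
        e_step(st)
        assert st.rho_i_hat[0] == pytest.approx(0.0, abs=1e-10)
        assert st.mu_i_hat[0] == pytest.approx(7.0, abs=1e-9)

    def test_cdss_match_direct_sums(self):
        st = manual_state(0.5, 2.0, [1.0, 3.0], [2, 3], [1.0, -0.5], [2.0, 1.0])
        e_step(st)
        assert st.T1 == pytest.approx(st.mu_i_hat.sum())
        assert st.T2 == pytest.approx(np.sum(st.nu_i_hat + st.mu_i_hat**2))


class TestMStep:
    def test_direct_substitution(self):
        st = manual_state(0.0, 1.0, [1.0, 1.0], [2, 2], [1.0, 3.0], [1.0, 9.0])
        st.mu_i_hat = np.array([1.0, 3.0])
        st.nu_i_hat = np.array([0.0, 0.0])
        st.T1 = 4.0
        st.T2 = 1.0 + 9.0
        st.T3 = np.array([2.0, 2.0])  # placeholder, sigma checked below
        m_step(st)
        assert st.mu_hat == pytest.approx(2.0)
        assert st.tau2_hat == pytest.approx(10.0 / 2 - 4.0)

    def test_sigma_from_cdss(self):
        # subject with y=(1,3), mu_i_hat=2, nu_i_hat=0: T3 = (1+1) -> sigma2=1
        st = manual_state(2.0, 1.0, [1.0, 1.0], [2, 2], [2.0, 2.0], [5.0, 5.0])
        st.mu_i_hat = np.array([2.0, 2.0])
        st.nu_i_hat = np.array([0.0, 0.0])
        st.T3 = st.n_i * (st.y2bar_i - 2 * st.mu_i_hat * st.ybar_i + st.mu_i_hat**2 + st.nu_i_hat)
        assert st.T3[0] == pytest.approx(2.0)
        st.T1, st.T2 = 4.0, 8.5
        m_step(st)
        assert st.sigma2_hat[0] == pytest.approx(1.0)

    def test_cdss_and_direct_m_step_identical(self, sim_table):
        table, _ = sim_table
        st = init_state(table)
        e_step(st)
        # direct forms computed independently of the stored CDSS
        mu_direct = st.mu_i_hat.mean()
        tau2_direct = np.mean(st.nu_i_hat + st.mu_i_hat**2) - mu_direct**2
        sigma2_direct = st.T3 / st.n_i
        m_step(st)
        assert st.mu_hat == mu_direct
        assert st.tau2_hat == tau2_direct
        np.testing.assert_array_equal(st.sigma2_hat, sigma2_direct)

    def test_fixed_point_identity(self, sim_table):
        table, _ = sim_table
        st = em_fit(table, tol=1e-14, max_iter=20000)
        before = (st.mu_hat, st.tau2_hat, st.sigma2_hat.copy())
        e_step(st)
        m_step(st)
        assert st.mu_hat == pytest.approx(before[0], rel=1e-8)
        assert st.tau2_hat == pytest.approx(before[1], rel=1e-7)
        np.testing.assert_allclose(st.sigma2_hat, before[2], rtol=1e-6)


class TestEMFit:
    def test_marginal_loglik_against_mvn_oracle(self):
        table, _ = simulate_population(4, 6, 1.0, 2.0, Sigma2Spec.fixed(0.7), seed=5)
        n, s1, s2 = table.suffstats()
        mu, tau2 = 0.8, 1.7
        sigma2 = np.array([0.5, 0.9, 1.4, 0.7])
        ll = marginal_loglik(mu, tau2, sigma2, n, s1 / n, s2 / n)
        ll_oracle = 0.0
        for k, sid in enumerate(table.subject_ids):
            y = table.values_for(sid)
            cov = sigma2[k] * np.eye(y.size) + tau2 * np.ones((y.size, y.size))
            ll_oracle += stats.multivariate_normal.logpdf(y, mean=np.full(y.size, mu), cov=cov)
        assert ll == pytest.approx(ll_oracle, rel=1e-10)

    def test_brute_force_mle_oracle(self):
        table, _ = simulate_population(3, 5, 2.0, 1.5, Sigma2Spec.from_ratios(0.3, 0.8), seed=13)
        per_subject = [table.values_for(s) for s in table.subject_ids]

        def nll(theta):
            mu, tau2 = theta[0], np.exp(theta[1])
            sig = np.exp(theta[2:])
            total = 0.0
            for k, y in enumerate(per_subject):
                cov = sig[k] * np.eye(y.size) + tau2 * np.ones((y.size, y.size))
                total += stats.multivariate_normal.logpdf(y, mean=np.full(y.size, mu), cov=cov)
            return -total

        x0 = np.array([float(np.mean(np.concatenate(per_subject))), 0.0, 0.0, 0.0, 0.0])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-12, fatol=1e-14, maxfev=100_000))
        res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                options=dict(xatol=1e-13, fatol=1e-15, maxfev=100_000))
        st = em_fit(table, tol=1e-14, max_iter=100_000)
        assert st.mu_hat == pytest.approx(res.x[0], abs=1e-4)
        assert st.tau2_hat == pytest.approx(np.exp(res.x[1]), abs=1e-4)
        np.testing.assert_allclose(st.sigma2_hat, np.exp(res.x[2:]), atol=1e-4)

    def test_parameter_recovery(self):
        table, params = simulate_population(
            100, 50, 10.0, 4.0, Sigma2Spec.from_ratios(0.1, 0.5), seed=17
        )
        st = em_fit(table)
        sig_true = np.array(list(params.sigma2_by_subject.values()))
        assert st.mu_hat == pytest.approx(10.0, rel=0.05)
        assert st.tau2_hat == pytest.approx(4.0, rel=0.10 + 2 / np.sqrt(100))
        assert st.sigma2_hat.mean() == pytest.approx(sig_true.mean(), rel=0.10)

    def test_degenerate_equal_means(self):
        rng = np.random.default_rng(2)
        records = [(f"S{k}", j, float(rng.normal(5.0, 1.0))) for k in range(20) for j in range(1, 30)]
        table = validate_table(records)
        st = em_fit(table)
        assert st.mu_hat == pytest.approx(5.0, abs=0.15)
        assert st.tau2_hat < 0.2

    def test_monotone_loglik(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            I = int(rng.integers(3, 10))
            n = int(rng.integers(2, 12))
            table, _ = simulate_population(
                I, n, float(rng.normal()), float(rng.uniform(0.2, 3)),
                Sigma2Spec.from_ratios(float(rng.uniform(0, 1)), float(rng.uniform(0.1, 2))),
                seed=int(rng.integers(2**31)),
            )
            st = em_fit(table, tol=1e-10, max_iter=300)
            path = np.array(st.loglik_path)
            assert np.all(np.diff(path) >= -1e-8 * (np.abs(path[:-1]) + 1))

    def test_homoscedastic_consistency_with_common_ml(self):
        # equal true WSV, plenty of data: per-subject estimates cluster on the
        # common maximum-likelihood value
        table, _ = simulate_population(40, 200, 0.0, 1.0, Sigma2Spec.fixed(0.5), seed=23)
        st = em_fit(table)
        assert st.sigma2_hat.mean() == pytest.approx(0.5, rel=0.05)
        assert st.sigma2_hat.std() < 0.1

    def test_requires_two_subjects(self):
        t = validate_table([("A", 1, 1.0), ("A", 2, 2.0)])
        with pytest.raises(DataError):
            em_fit(t)


class TestSemaUpdate:
    def test_no_information_update(self, sim_table):
        table, _ = sim_table
        st = em_fit(table)
        mu_before = st.mu_hat
        sid = table.subject_ids[0]
        k = st.position(sid)
        # feeding values at the current subject posterior mean barely moves mu
        for _ in range(3):
            sema_update(st, sid, float(st.mu_i_hat[k]))
        assert st.mu_hat == pytest.approx(mu_before, abs=0.02)

    def test_agreement_with_batch_on_large_stream(self):
        table, _ = simulate_population(
            200, 50, 10.0, 4.0, Sigma2Spec.from_ratios(0.25, 0.5), seed=29
        )
        batch = em_fit(table)
        streamed = fit_stream(table)
        assert streamed.mu_hat == pytest.approx(batch.mu_hat, rel=0.05)
        assert streamed.tau2_hat == pytest.approx(batch.tau2_hat, rel=0.05)

    def test_agreement_improves_with_volume(self):
        errs = {}
        for label, (I, n) in {"small": (10, 5), "large": (200, 50)}.items():
            rel = []
            for seed in (1, 2, 3):
                table, _ = simulate_population(
                    I, n, 0.0, 1.0, Sigma2Spec.from_ratios(0.2, 0.5), seed=seed
                )
                b = em_fit(table)
                s = fit_stream(table, batch_size=2 * n)
                rel.append(abs(s.tau2_hat - b.tau2_hat) / b.tau2_hat
                           + abs(s.mu_hat - b.mu_hat) / (abs(b.mu_hat) + 1))
            errs[label] = np.mean(rel)
        assert errs["large"] < errs["small"]

    def test_memory_contract(self):
        table, _ = simulate_population(3, 5, 0.0, 1.0, Sigma2Spec.fixed(0.5), seed=1)
        st = em_fit(table)
        rng = np.random.default_rng(0)
        for _ in range(500):
            sema_update(st, "S1", float(rng.normal()))
        # state arrays scale with subjects, never with observation count
        assert st.sigma2_hat.size == 3
        assert st.ybar_i.size == 3

    def test_new_subject_appended(self, sim_table):
        table, _ = sim_table
        st = em_fit(table)
        I0 = st.I
        sema_update(st, "fresh", 9.5)
        assert st.I == I0 + 1
        assert st.n_i[st.position("fresh")] == 1


class TestPredictive:
    def test_no_history_case(self):
        st = manual_state(0.0, 1.0, [1.0], [0], [0.0], [0.0])
        lo, hi = dynamic_band_em(st, "S0", 1, alpha=0.05)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(-z * np.sqrt(2.0), abs=1e-9)
        assert hi == pytest.approx(z * np.sqrt(2.0), abs=1e-9)
        assert hi == pytest.approx(2.7718, abs=1e-3)

    def test_long_history_limit(self):
        st = manual_state(0.0, 1.0, [1.0], [10_000_000], [2.0], [5.0])
        centre, sd = predictive_normal(st, "S0", 10_000_001)
        assert centre == pytest.approx(2.0, abs=1e-4)
        assert sd == pytest.approx(1.0, abs=1e-4)

    def test_band_matches_normal_quantiles(self, rng):
        # formula limits equal ppf quantiles of the predictive normal
        for _ in range(200):
            mu = float(rng.normal(0, 5))
            tau2 = float(rng.uniform(0.1, 5))
            sigma2 = float(rng.uniform(0.1, 5))
            j = int(rng.integers(1, 50))
            ybar = float(rng.normal(0, 5))
            alpha = float(rng.uniform(0.01, 0.2))
            st = manual_state(mu, tau2, [sigma2], [j - 1], [ybar], [ybar**2 + 1])
            lo, hi = dynamic_band_em(st, "S0", j, alpha)
            centre, sd = predictive_normal(st, "S0", j)
            assert lo == pytest.approx(stats.norm.ppf(alpha / 2, centre, sd), abs=1e-10)
            assert hi == pytest.approx(stats.norm.ppf(1 - alpha / 2, centre, sd), abs=1e-10)

    def test_score_at_centre_and_band_edge(self):
        st = manual_state(0.3, 1.2, [0.8], [6], [1.1], [2.5])
        centre, _ = predictive_normal(st, "S0", 7)
        assert predictive_score_em(st, "S0", 7, centre) == pytest.approx(1.0)
        lo, hi = dynamic_band_em(st, "S0", 7, alpha=0.05)
        assert predictive_score_em(st, "S0", 7, hi) == pytest.approx(0.05, abs=1e-9)
        assert predictive_score_em(st, "S0", 7, lo) == pytest.approx(0.05, abs=1e-9)

    def test_history_mismatch(self):
        st = manual_state(0.0, 1.0, [1.0], [3], [0.5], [1.0])
        with pytest.raises(DataError, match="history mismatch"):
            predictive_normal(st, "S0", 6)

    def test_pit_uniform_at_true_parameters(self, rng):
        mu, tau2, sigma2, m = 0.0, 1.0, 0.5, 10
        reps = 4000
        mu_i = rng.normal(mu, np.sqrt(tau2), reps)
        ybar = mu_i + rng.normal(0, np.sqrt(sigma2 / m), reps)
        y_new = mu_i + rng.normal(0, np.sqrt(sigma2), reps)
        scores = np.empty(reps)
        for r in range(reps):
            st = manual_state(mu, tau2, [sigma2], [m], [ybar[r]], [ybar[r] ** 2 + sigma2])
            scores[r] = predictive_score_em(st, "S0", m + 1, y_new[r])
        assert stats.kstest(scores, "uniform").pvalue > 1e-3

    def test_posterior_matches_e_step_at_convergence(self, sim_table):
        # the predictive centre/variance and the E-step shrinkage agree
        table, _ = sim_table
        st = em_fit(table, tol=1e-12, max_iter=5000)
        sid = table.subject_ids[3]
        k = st.position(sid)
        j = int(st.n_i[k]) + 1
        centre, sd = predictive_normal(st, sid, j)
        assert centre == pytest.approx(st.mu_i_hat[k], rel=1e-6)
        assert sd**2 - st.sigma2_hat[k] == pytest.approx(st.nu_i_hat[k], rel=1e-6)
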