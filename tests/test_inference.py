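"""DRAM sampler correctness, convergence diagnostics, posterior summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dsmspread.geometry import Domain, SwarmMap
from dsmspread.inference import (
    ChainState,
    CompiledLikelihood,
    MODEL_TRANSFORM,
    ParamTransform,
    dram_sample,
    gelman_rhat,
    log_posterior,
    summarize,
)
from dsmspread.observation import Catchability, TrapRecord, records_to_frame, sampling_time
from dsmspread.pde import PDEParams, ReleaseEvent, solve
from dsmspread.priors import ExpertPrior, PARAM_NAMES, Prior, PriorSet
from dsmspread.synthetic import truth_vector


def _wt_priors():
    experts = [
        ExpertPrior("E1", "WT", Prior("beta", (12, 2)),
                    Prior("lognormal", (np.log(80), 0.6))),
        ExpertPrior("E2", "WT", Prior("beta", (8, 2)),
                    Prior("lognormal", (np.log(150), 0.8))),
    ]
    return PriorSet.from_experts(experts)


class TestParamTransform:
    def test_round_trip_and_jacobian(self):
        theta = truth_vector()
        z = MODEL_TRANSFORM.forward(theta)
        assert np.allclose(MODEL_TRANSFORM.inverse(z), theta)
        # numeric Jacobian determinant vs analytic
        eps = 1e-6
        diag = []
        for i in range(7):
            zp = z.copy()
            zp[i] += eps
            diag.append((MODEL_TRANSFORM.inverse(zp)[i] - theta[i]) / eps)
        assert MODEL_TRANSFORM.log_jacobian(z) == pytest.approx(
            np.log(diag).sum(), abs=1e-4
        )


class TestDramOnKnownTargets:
    def test_recovers_standard_normal(self):
        def lt(x):
            return -0.5 * x @ x

        st_ = dram_sample(
            lt, np.array([[1.0, -1.0], [0.5, 2.0], [-2.0, 0.0]]),
            0.5 * np.eye(2), n_iter=5000, burn_in=1000, seed=3,
        )
        flat = st_.flat()
        # MC error inflated by autocorrelation; 3x a conservative se
        assert np.abs(flat.mean(axis=0)).max() < 0.1
        cov = np.cov(flat.T)
        assert np.allclose(np.diag(cov), 1.0, rtol=0.1)
        assert abs(cov[0, 1]) < 0.1

    def test_stationary_proposal_always_accepted(self):
        # the MH ratio of identical densities is 1: a degenerate proposal
        # covariance keeps the chain glued to its start with acceptance 1
        def lt(x):
            return -0.5 * x @ x

        st_ = dram_sample(
            lt, np.zeros((1, 2)), 1e-30 * np.eye(2),
            n_iter=200, burn_in=0, adapt_every=0, seed=0,
        )
        assert st_.accept_first[0] == 200
        assert np.allclose(st_.draws, 0.0)

    def test_adaptation_learns_target_correlation(self):
        rho = 0.9
        icov = np.linalg.inv(np.array([[1, rho], [rho, 1]]))

        def lt(x):
            return -0.5 * x @ icov @ x

        st_ = dram_sample(
            lt, np.zeros((1, 2)), np.eye(2) * 0.3,
            n_iter=4000, burn_in=0, adapt_every=200, seed=5,
        )
        _, last_cov = st_.cov_history[0][-1]
        corr = last_cov[0, 1] / np.sqrt(last_cov[0, 0] * last_cov[1, 1])
        assert corr > 0.5

    def test_delayed_stage_contributes_acceptances(self):
        def lt(x):
            return -0.5 * x @ x

        st_ = dram_sample(
            lt, np.zeros((1, 2)), 25.0 * np.eye(2),  # oversized first stage
            n_iter=2000, burn_in=0, seed=11,
        )
        assert st_.accept_delayed[0] > 0

    def test_detailed_balance_on_discrete_analogue(self):
        # 3-state analogue with the same two-stage acceptance rule: the
        # empirical occupancy must match the target to ~1% at 1e6 steps
        target = np.array([0.5, 0.3, 0.2])
        rng = np.random.default_rng(8)
        x = 0
        counts = np.zeros(3)
        n = 1_000_000
        others = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
        us = rng.random((n, 4))
        for k in range(n):
            y = others[x][int(us[k, 0] < 0.5)]
            a1_xy = min(1.0, target[y] / target[x])
            if us[k, 1] < a1_xy:
                x = y
            else:
                z = others[x][int(us[k, 2] < 0.5)]
                a1_zy = min(1.0, target[y] / target[z])
                num = target[z] * (1 - a1_zy)
                den = target[x] * (1 - a1_xy)
                if den > 0 and us[k, 3] < min(1.0, num / den):
                    x = z
            counts[x] += 1
        freq = counts / n
        assert np.abs(freq - target).max() < 0.01


class TestGelmanRhat:
    def test_iid_chains_converge(self, rng):
        chains = rng.normal(size=(3, 5000, 2))
        assert np.all(gelman_rhat(chains) < 1.01)

    def test_separated_chains_flagged(self, rng):
        c1 = rng.normal(0.0, 1.0, size=(1, 2000, 1))
        c2 = rng.normal(10.0, 1.0, size=(1, 2000, 1))
        assert gelman_rhat(np.concatenate([c1, c2]))[0] > 1.5

    def test_duplicated_chain_is_unity(self, rng):
        c = rng.normal(size=(1, 3000, 1))
        r = gelman_rhat(np.concatenate([c, c]))[0]
        assert r == pytest.approx(1.0, abs=0.02)

    def test_zero_variance_reports_nan(self):
        chains = np.ones((2, 100, 1))
        assert np.isnan(gelman_rhat(chains)[0])

    def test_too_few_chains_rejected(self, rng):
        with pytest.raises(ValueError):
            gelman_rhat(rng.normal(size=(1, 100, 1)))

    def test_agrees_with_arviz_split_rhat(self, rng):
        import arviz as az

        chains = rng.normal(size=(3, 400)) + np.array([[0.0], [0.3], [0.6]])
        ours = gelman_rhat(chains[..., None])[0]
        theirs = float(az.rhat(az.convert_to_dataset(chains), method="split")["x"])
        assert ours == pytest.approx(theirs, rel=1e-6)


class TestSummarize:
    def _state(self, draws):
        n_chains, n_iter, dim = draws.shape
        return ChainState(
            draws=draws,
            log_post=np.zeros((n_chains, n_iter)),
            accept_first=np.zeros(n_chains, int),
            accept_delayed=np.zeros(n_chains, int),
            cov_history=[[] for _ in range(n_chains)],
            param_names=tuple(f"x{i}" for i in range(dim)),
            burn_in=0,
        )

    def test_constant_chain_summary(self):
        st_ = self._state(np.full((2, 100, 1), 3.14))
        row = summarize(st_, include_ess=False).iloc[0]
        assert row["mean"] == row["q05"] == row["q95"] == 3.14

    def test_uniform_quantiles(self, rng):
        st_ = self._state(rng.uniform(size=(2, 50_000, 1)))
        row = summarize(st_, include_ess=False).iloc[0]
        assert row["q05"] == pytest.approx(0.05, abs=0.01)
        assert row["q95"] == pytest.approx(0.95, abs=0.01)

    def test_quantiles_commute_with_monotone_transform(self, rng):
        # mu draws -> daily mortality: quantiles commute, means need not
        mu = rng.gamma(2.0, 0.5, size=(2, 20_000, 1))
        st_ = self._state(mu)
        st_.param_names = ("mu",)
        summ = summarize(st_, include_ess=False).set_index("parameter")
        daily = 1 - np.exp(-mu.reshape(-1))
        assert summ.loc["mu_daily", "q05"] == pytest.approx(
            1 - np.exp(-summ.loc["mu", "q05"]), abs=1e-9
        )
        assert summ.loc["mu_daily", "q95"] == pytest.approx(
            np.quantile(daily, 0.95), abs=1e-3
        )
        # the transformed mean differs from the transform of the mean
        assert summ.loc["mu_daily", "mean"] != pytest.approx(
            1 - np.exp(-summ.loc["mu", "mean"]), abs=1e-4
        )


class TestLogPosterior:
    def _setup(self, rng):
        domain = Domain((0, 0), (400, 400), cell_size=10.0)
        swarms = SwarmMap(np.array([[180.0, 220.0], [260.0, 180.0]]), sigma=30.0)
        releases = pd.DataFrame(
            {"release_id": ["r1"], "easting": [205.0], "northing": [205.0],
             "n_released": [1000.0]}
        )
        recs = []
        for k in range(10):
            tt = ["ss", "psc", "cfr"][k % 3]
            loc = (float(rng.uniform(150, 260)), float(rng.uniform(150, 260)))
            recs.append(TrapRecord("r1", f"t{k}", tt, loc, 1 + k % 3,
                                   int(rng.integers(0, 4))))
        return domain, swarms, releases, records_to_frame(recs)

    def test_out_of_support_is_minus_inf(self, rng):
        domain, swarms, releases, records = self._setup(rng)
        priors = _wt_priors()
        theta = truth_vector()
        theta[2] = -0.1  # negative mortality
        assert log_posterior(theta, records, releases, domain, swarms, priors) == -np.inf

    def test_no_records_equals_log_prior(self, rng):
        domain, swarms, releases, _ = self._setup(rng)
        priors = _wt_priors()
        theta = truth_vector()
        empty = records_to_frame([])
        lp = log_posterior(theta, empty, releases, domain, swarms, priors)
        assert lp == pytest.approx(priors.logpdf(theta))

    def test_difference_matches_straight_line_reimplementation(self, rng):
        # independent path: per-release PDE solve + brute-force latent sums
        from scipy.stats import binom, poisson

        domain, swarms, releases, records = self._setup(rng)
        priors = _wt_priors()

        def straight_line(theta):
            D, alpha, mu, sigma, p_ss, p_psc, p_cfr = theta
            params = PDEParams(D=D, alpha=alpha, mu=mu, sigma=sigma)
            times = sorted(
                {sampling_time(t, d) for t, d in
                 zip(records["trap_type"], records["day"])}
            )
            f = solve(ReleaseEvent((205.0, 205.0), 1000.0), params, swarms,
                      domain, times)
            p_of = {"ss": p_ss, "psc": p_psc, "cfr": p_cfr}
            total = priors.logpdf(theta)
            for row in records.itertuples():
                lam = f.value_at((row.easting, row.northing),
                                 sampling_time(row.trap_type, row.day))
                ns = np.arange(row.count, 400)
                marg = (binom.pmf(row.count, ns, p_of[row.trap_type])
                        * poisson.pmf(ns, lam)).sum()
                total += np.log(marg)
            return total

        t1 = truth_vector()
        t2 = t1 * np.array([1.2, 0.8, 1.3, 0.9, 1.1, 0.9, 1.2])
        lp1 = log_posterior(t1, records, releases, domain, swarms, priors)
        lp2 = log_posterior(t2, records, releases, domain, swarms, priors)
        assert lp1 - lp2 == pytest.approx(straight_line(t1) - straight_line(t2),
                                          abs=1e-6)

    def test_pathological_step_budget_warns_not_crashes(self, rng):
        domain, swarms, releases, records = self._setup(rng)
        compiled = CompiledLikelihood(records, releases, domain, swarms, max_steps=10)
        theta = truth_vector()
        theta[0] = 5e5  # enormous diffusion
        with pytest.warns(RuntimeWarning, match="sub-steps"):
            assert compiled.loglik(theta) == -np.inf
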