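"""Persistence curves, absence radii, extent masks, held-out validation."""

import numpy as np
import pandas as pd
import pytest

from dsmspread.geometry import Domain, SwarmMap
from dsmspread.observation import Catchability, sample_catches
from dsmspread.pde import PDEParams, ReleaseEvent, solve
from dsmspread.prediction import (
    AbsenceRadius,
    PredictionEnsemble,
    absence_radius,
    expected_extent,
    persistence_curve,
    validate,
)


def _theta(D=130.0, alpha=0.0, mu=0.2, sigma=30.0, p=(0.29, 0.18, 0.03)):
    return np.array([D, alpha, mu, sigma, *p])


def _ensemble(small_domain, draws, n0=5000.0, horizon=20.0, loc=(255.0, 255.0)):
    return PredictionEnsemble(
        draws=draws,
        release=ReleaseEvent(loc, n0),
        domain=small_domain,
        swarms=None,
        source="fixed",
        horizon=horizon,
    )


class TestPersistence:
    def test_fixed_mortality_crossing_matches_closed_form(self, small_domain):
        # reflecting boundaries: total mass is exactly N0 e^{-mu t}; a cohort
        # of 5000 at mu=0.852/day crosses 1 at ln(5000)/0.852 ~ 10 days
        mu = 0.852
        ens = _ensemble(small_domain, _theta(mu=mu), horizon=15.0)
        res = persistence_curve(ens, threshold=1.0)
        expect = np.log(5000.0) / mu
        assert res.crossing_day[0] == pytest.approx(expect, rel=1e-3)
        assert not res.censored[0]
        assert expect == pytest.approx(10.0, abs=0.01)

    def test_threshold_at_release_size_crosses_immediately(self, small_domain):
        ens = _ensemble(small_domain, _theta(), horizon=5.0)
        res = persistence_curve(ens, threshold=5000.0)
        assert res.crossing_day[0] == 0.0

    def test_immortal_draw_right_censored(self, small_domain):
        ens = _ensemble(small_domain, _theta(mu=0.0), horizon=8.0)
        res = persistence_curve(ens, threshold=1.0)
        assert res.censored[0]
        assert res.crossing_day[0] == 8.0

    def test_log_linear_decay_of_summary(self, small_domain):
        ens = _ensemble(small_domain, _theta(mu=0.3), horizon=10.0)
        res = persistence_curve(ens)
        logm = np.log(res.summary()["mean"].to_numpy())
        diffs = np.diff(logm)
        assert np.allclose(diffs, -0.3, atol=1e-6)

    def test_persistence_day_monotone_in_mortality(self, small_domain):
        days = []
        for mu in (0.3, 0.6, 1.2):
            ens = _ensemble(small_domain, _theta(mu=mu), horizon=40.0)
            days.append(persistence_curve(ens).crossing_day[0])
        assert days[0] > days[1] > days[2]


class TestAbsenceRadius:
    def test_zero_field_radius_zero(self, small_domain):
        ens = _ensemble(small_domain, _theta(mu=50.0), horizon=5.0)
        # by day 2 at mu=50 the field is numerically zero everywhere
        res = absence_radius(ens, time=2.0, prob=0.99)
        assert res.radius == 0.0 and res.reached

    def test_unreachable_level_flagged(self, small_domain):
        # release near the domain edge: the certifiable radius is small and
        # a broadly spread immortal cohort cannot reach the 0.99 level
        ens = _ensemble(small_domain, _theta(mu=0.0, D=300.0), horizon=5.0,
                        loc=(35.0, 255.0))
        res = absence_radius(ens, time=3.0, prob=0.99)
        assert not res.reached
        assert res.radius <= 35.0

    def test_brute_force_scan_on_hand_built_field(self, small_domain):
        # compare against an exhaustive exp(-tail sum) scan over radii
        ens = _ensemble(small_domain, _theta(D=150.0, mu=0.9), horizon=5.0)
        t, prob = 3.0, 0.99
        res = absence_radius(ens, t, prob)
        lam = ens.solve_draw(0, [t])[0]
        X, Y = small_domain.cell_centers()
        dist = np.hypot(X - 255.0, Y - 255.0)
        radii = np.unique(dist.ravel())
        best = None
        for r in radii:
            p0 = np.exp(-lam[dist > r].sum())
            if p0 >= prob:
                best = r
                break
        assert res.radius == pytest.approx(best)
        assert res.prob >= prob

    def test_radius_shrinks_with_time_past_balance_point(self, small_domain):
        # for a decaying cohort the radius r(t) ~ sqrt(4Dt (ln(M0/eps) - mu t))
        # grows while diffusion wins, then contracts once mortality dominates
        # (the balance point here is near t = 7.7 d); check the contraction
        D, mu = 130.0, 0.852
        ens = _ensemble(small_domain, _theta(D=D, mu=mu), horizon=16.0)
        radii = [absence_radius(ens, t, 0.99).radius for t in (8.0, 10.5, 13.0)]
        assert radii[0] >= radii[1] >= radii[2]
        assert radii[2] < radii[0]

    def test_level_validation(self, small_domain):
        ens = _ensemble(small_domain, _theta(), horizon=5.0)
        with pytest.raises(ValueError):
            absence_radius(ens, 1.0, prob=1.0)


class TestExpectedExtent:
    def test_day_zero_extent_is_release_cell(self, small_domain):
        ens = _ensemble(small_domain, _theta(), horizon=5.0)
        mask, poly = expected_extent(ens, 0.0)
        i, j = small_domain.cell_index((255.0, 255.0))
        expect = np.zeros(small_domain.shape, bool)
        expect[i, j] = True
        assert np.array_equal(mask, expect)
        assert poly is not None and poly.area == pytest.approx(100.0)

    def test_extinct_field_empty_mask(self, small_domain):
        ens = _ensemble(small_domain, _theta(mu=2.0), horizon=10.0)
        mask, poly = expected_extent(ens, 8.0)  # 5000 e^{-16} << 1
        assert not mask.any() and poly is None

    def test_mask_equals_thresholding_oracle(self, small_domain):
        ens = _ensemble(small_domain, _theta(D=200.0, mu=0.5), horizon=6.0)
        mask, _ = expected_extent(ens, 2.0)
        lam = ens.solve_draw(0, [2.0])[0]
        assert np.array_equal(mask, lam >= 1.0)


class TestValidate:
    def _held_out(self, small_domain, theta, n0, seed, n_traps=25, n_days=6):
        rng = np.random.default_rng(seed)
        params = PDEParams(D=theta[0], alpha=theta[1], mu=theta[2], sigma=theta[3])
        catch = Catchability(*theta[4:7])
        from dsmspread.observation import sampling_time

        times = sorted(
            {sampling_time("ss", d) for d in range(n_days)}
            | {sampling_time("psc", d) for d in range(1, n_days + 1)}
        )
        field = solve(ReleaseEvent((255.0, 255.0), n0), params, None,
                      small_domain, times)
        traps = pd.DataFrame(
            {
                "trap_id": [f"t{k}" for k in range(n_traps)],
                "trap_type": [["ss", "psc", "cfr"][k % 3] for k in range(n_traps)],
                "easting": rng.uniform(200, 320, n_traps),
                "northing": rng.uniform(200, 320, n_traps),
            }
        )
        return sample_catches({"v1": field}, traps, n_days, catch, rng)

    def test_rmse_formula_oracle(self, small_domain):
        theta = _theta(mu=0.4)
        ens = _ensemble(small_domain, theta, n0=3000.0, horizon=10.0)
        held = self._held_out(small_domain, theta, 3000.0, seed=4)
        rep = validate(ens, held)
        resid = held["count"].to_numpy() - rep.table["pred_mean"].to_numpy()
        assert rep.rmse == pytest.approx(np.sqrt(np.mean(resid**2)))
        assert rep.n_total == len(held)
        assert 0 <= rep.n_outside <= rep.n_total

    def test_generating_parameters_are_calibrated(self, small_domain):
        # with the generating ensemble the expected outside-fraction equals
        # the sum of exact Poisson tail masses; observed must agree within
        # binomial noise, and coverage is at least nominal (discrete counts)
        from scipy import stats

        theta = _theta(mu=0.25)
        n0 = 4000.0
        ens = _ensemble(small_domain, theta, n0=n0, horizon=10.0)
        held = self._held_out(small_domain, theta, n0, seed=10, n_traps=60)
        rep = validate(ens, held)
        lo = rep.table["pred_q05"].to_numpy()
        hi = rep.table["pred_q95"].to_numpy()
        m = rep.table["pred_mean"].to_numpy()
        q_out = stats.poisson.cdf(lo - 1, m) + stats.poisson.sf(hi, m)
        expect = q_out.mean()
        assert expect <= 0.10 + 1e-9
        se = np.sqrt(expect * (1 - expect) / rep.n_total)
        assert abs(rep.outside_fraction - expect) <= 3 * se + 1e-9

    def test_intervals_widen_with_parameter_uncertainty(self, small_domain):
        theta = _theta(mu=0.3)
        held = self._held_out(small_domain, theta, 4000.0, seed=2)
        fixed = _ensemble(small_domain, theta, n0=4000.0, horizon=10.0)
        jitter = np.vstack([theta * f for f in (0.8, 0.9, 1.0, 1.1, 1.25)])
        jitter[:, 4:] = np.clip(jitter[:, 4:], 0.01, 0.99)
        wide = _ensemble(small_domain, jitter, n0=4000.0, horizon=10.0)
        r_fixed = validate(fixed, held)
        r_wide = validate(wide, held)
        w_fixed = (r_fixed.table["pred_q95"] - r_fixed.table["pred_q05"]).sum()
        w_wide = (r_wide.table["pred_q95"] - r_wide.table["pred_q05"]).sum()
        assert w_wide >= w_fixed

    def test_empty_held_out_rejected(self, small_domain):
        ens = _ensemble(small_domain, _theta(), horizon=5.0)
        with pytest.raises(ValueError):
            validate(ens, pd.DataFrame(columns=["release_id", "trap_id", "trap_type",
                                                "easting", "northing", "day", "count"]))
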