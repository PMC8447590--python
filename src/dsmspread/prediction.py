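"""Predictive simulation of a released cohort: persistence, extent, validation.

Given an ensemble of parameter draws — posterior chains for the wild-type
strain, or the evidence-weighted pool of expert priors for the modified
strain — these routines propagate a release scenario (by default a single
cohort of 5000 males) through the dispersal PDE and summarise:

* the **persistence curve**: the distribution over draws of the expected
  total number of surviving mosquitoes per day, and the day on which it
  falls below a threshold (1 mosquito by default);
* the **absence radius**: the smallest distance from the release point
  beyond which, under the Poisson abundance field, the probability of
  finding zero mosquitoes is at least a set level (0.99 by default);
* the **expected extent**: the set of cells whose mean expected count is
  at least 1;
* **validation** against held-out trap records: per trap-day predictive
  intervals from the Poisson observation model mixed over draws, the
  count of observations falling outside their 90% interval, and the RMSE
  between observed counts and predictive means.

Thresholding for the persistence day uses the *expected* field (the
quantity the PDE solves for), not realised Poisson counts; predictive
intervals for counts are central and equal-tailed with boundary ties
counted as inside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import Domain, SwarmMap
from .inference import ChainState, CompiledLikelihood
from .observation import validate_records, record_times, TRAP_TYPES
from .pde import PDEParams, ReleaseEvent, solve, total_abundance
from .priors import PARAM_NAMES, PriorSet

DEFAULT_N_RELEASED = 5000.0
DEFAULT_HORIZON_DAYS = 60.0
DEFAULT_ENSEMBLE_SIZE = 500


@dataclass
class PredictionEnsemble:
    """Parameter draws plus the release scenario they are propagated through.

    ``draws`` has shape ``(n_draws, 7)`` in the canonical order
    ``(D, alpha, mu, sigma, p_ss, p_psc, p_cfr)``; ``source`` records
    where the draws came from ("posterior", "pooled_prior", "fixed").
    """

    draws: np.ndarray
    release: ReleaseEvent
    domain: Domain
    swarms: SwarmMap | None
    source: str = "posterior"
    horizon: float = DEFAULT_HORIZON_DAYS
    max_steps: int = 200_000

    def __post_init__(self) -> None:
        self.draws = np.atleast_2d(np.asarray(self.draws, float))
        if self.draws.shape[0] == 0:
            raise ValueError("ensemble must contain at least one draw")
        if self.draws.shape[1] != len(PARAM_NAMES):
            raise ValueError(f"draws must have {len(PARAM_NAMES)} columns")
        if self.release.n_released <= 0:
            raise ValueError("release size must be positive")

    @classmethod
    def from_chains(
        cls,
        state: ChainState,
        release: ReleaseEvent,
        domain: Domain,
        swarms: SwarmMap | None,
        n_draws: int = DEFAULT_ENSEMBLE_SIZE,
        seed=None,
        **kwargs,
    ) -> "PredictionEnsemble":
        """Thin the post-burn-in chains to an ensemble of fixed size."""
        flat = state.flat()
        rng = np.random.default_rng(seed)
        if n_draws >= len(flat):
            take = flat
        else:
            idx = np.sort(rng.choice(len(flat), size=n_draws, replace=False))
            take = flat[idx]
        return cls(take, release, domain, swarms, source="posterior", **kwargs)

    @classmethod
    def from_prior(
        cls,
        priors: PriorSet,
        release: ReleaseEvent,
        domain: Domain,
        swarms: SwarmMap | None,
        n_draws: int = DEFAULT_ENSEMBLE_SIZE,
        seed=None,
        **kwargs,
    ) -> "PredictionEnsemble":
        rng = np.random.default_rng(seed)
        return cls(
            priors.sample(rng, size=n_draws),
            release,
            domain,
            swarms,
            source="pooled_prior",
            **kwargs,
        )

    @classmethod
    def from_fixed(cls, theta, release, domain, swarms, **kwargs) -> "PredictionEnsemble":
        return cls(np.atleast_2d(theta), release, domain, swarms, source="fixed", **kwargs)

    def _pde_params(self, k: int) -> PDEParams:
        D, alpha, mu, sigma = self.draws[k, :4]
        return PDEParams(D=D, alpha=alpha, mu=mu, sigma=sigma)

    def solve_draw(self, k: int, output_times) -> np.ndarray:
        """Abundance fields (n_times, nx, ny) for draw ``k``."""
        f = solve(
            self.release,
            self._pde_params(k),
            self.swarms,
            self.domain,
            output_times,
            max_steps=self.max_steps,
        )
        return f.values


@dataclass
class PersistenceResult:
    """Per-day distribution of expected total abundance across draws."""

    days: np.ndarray
    totals: np.ndarray  # (n_draws, n_days)
    threshold: float
    crossing_day: np.ndarray  # per draw; horizon where censored
    censored: np.ndarray  # per draw bool: never crossed within horizon

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day": self.days,
                "mean": self.totals.mean(axis=0),
                "q05": np.quantile(self.totals, 0.05, axis=0),
                "q95": np.quantile(self.totals, 0.95, axis=0),
            }
        )

    def crossing_quantile(self, q: float) -> float:
        """Quantile of the threshold-crossing day (censored draws at horizon)."""
        return float(np.quantile(self.crossing_day, q))


def _log_interp_crossing(days: np.ndarray, totals: np.ndarray, threshold: float):
    """Day each curve first drops below threshold; log-linear interpolation."""
    n_draws, _ = totals.shape
    horizon = days[-1]
    crossing = np.full(n_draws, horizon)
    censored = np.zeros(n_draws, dtype=bool)
    logt = np.log(np.maximum(totals, 1e-300))
    logth = np.log(threshold)
    for k in range(n_draws):
        below = np.nonzero(totals[k] < threshold)[0]
        if below.size == 0:
            censored[k] = True
            continue
        b = below[0]
        if b == 0:
            crossing[k] = days[0]
            continue
        a = b - 1
        frac = (logth - logt[k, a]) / (logt[k, b] - logt[k, a])
        crossing[k] = days[a] + frac * (days[b] - days[a])
    return crossing, censored


def persistence_curve(
    ensemble: PredictionEnsemble,
    threshold: float = 1.0,
    day_step: float = 1.0,
) -> PersistenceResult:
    """Expected-total-abundance curves and threshold-crossing days.

    Each draw's PDE solution is totalled on a daily grid out to the
    ensemble horizon; the crossing day interpolates linearly on the log
    scale (the decay is exponential, so the curve is a straight line
    there).  Draws that never cross within the horizon are reported as
    right-censored at the horizon.
    """
    days = np.arange(0.0, ensemble.horizon + 0.5 * day_step, day_step)
    n = len(ensemble.draws)
    totals = np.empty((n, len(days)))
    for k in range(n):
        vals = ensemble.solve_draw(k, days)
        totals[k] = vals.sum(axis=(1, 2))
    crossing, censored = _log_interp_crossing(days, totals, threshold)
    return PersistenceResult(
        days=days, totals=totals, threshold=threshold,
        crossing_day=crossing, censored=censored,
    )


@dataclass(frozen=True)
class AbsenceRadius:
    """Smallest radius with P(no mosquito beyond it) >= the target level."""

    radius: float
    prob: float  # achieved probability at that radius
    reached: bool  # False when the target level is unreachable in-domain


def absence_radius(
    ensemble: PredictionEnsemble, time: float, prob: float = 0.99
) -> AbsenceRadius:
    """Radius beyond which no mosquito is found with probability >= ``prob``.

    Under the Poisson field the number of mosquitoes beyond radius ``r``
    is Poisson with mean the tail sum of lambda, so

        P(zero beyond r) = E_draws[ exp(-sum_{cells: dist > r} lambda) ].

    Candidate radii are the sorted distances from the release point to
    cell centres (grid-aligned), capped at the distance from the release
    point to the nearest domain edge — beyond that a full disk is no
    longer contained in the domain, so absence outside it cannot be
    certified.  If no certifiable radius reaches the level, the largest
    one is returned flagged unreached.
    """
    if not (0.0 < prob < 1.0):
        raise ValueError("prob must be in (0, 1)")
    X, Y = ensemble.domain.cell_centers()
    rel = ensemble.release.location
    dist = np.hypot(X - rel[0], Y - rel[1]).ravel()
    order = np.argsort(dist)
    d_sorted = dist[order]

    n = len(ensemble.draws)
    p0 = np.zeros(len(d_sorted))
    for k in range(n):
        lam = ensemble.solve_draw(k, [time])[0].ravel()[order]
        # tail[m] = mass in cells strictly after sorted position m
        tail = np.concatenate([np.cumsum(lam[::-1])[::-1][1:], [0.0]])
        p0 += np.exp(-tail)
    p0 /= n

    (x0, y0), (w, h) = ensemble.domain.origin, ensemble.domain.extent
    certifiable = min(rel[0] - x0, x0 + w - rel[0], rel[1] - y0, y0 + h - rel[1])
    uniq = np.unique(d_sorted)
    uniq = uniq[uniq <= certifiable]
    if uniq.size == 0:
        uniq = d_sorted[:1]
    # achieved probability at radius uniq[m]: tail past the last tied cell
    last_idx = np.searchsorted(d_sorted, uniq, side="right") - 1
    probs = p0[last_idx]
    ok = np.nonzero(probs >= prob)[0]
    if ok.size == 0:
        return AbsenceRadius(radius=float(uniq[-1]), prob=float(probs[-1]), reached=False)
    m = ok[0]
    return AbsenceRadius(radius=float(uniq[m]), prob=float(probs[m]), reached=True)


def expected_extent(
    ensemble: PredictionEnsemble, time: float, threshold: float = 1.0
):
    """Cells whose mean-over-draws expected count reaches the threshold.

    Returns ``(mask, polygon)``: a boolean (nx, ny) mask and a shapely
    (multi)polygon of the union of the selected cells (None when empty).
    """
    n = len(ensemble.draws)
    nx, ny = ensemble.domain.shape
    mean_field = np.zeros((nx, ny))
    for k in range(n):
        mean_field += ensemble.solve_draw(k, [time])[0]
    mean_field /= n
    mask = mean_field >= threshold
    polygon = None
    if mask.any():
        from shapely.geometry import box
        from shapely.ops import unary_union

        h = ensemble.domain.cell_size
        x0, y0 = ensemble.domain.origin
        cells = [
            box(x0 + i * h, y0 + j * h, x0 + (i + 1) * h, y0 + (j + 1) * h)
            for i, j in zip(*np.nonzero(mask))
        ]
        polygon = unary_union(cells)
    return mask, polygon


@dataclass
class ValidationReport:
    """Held-out predictive check: intervals, coverage, RMSE."""

    table: pd.DataFrame  # per record: predictive mean/median/interval, outside
    n_outside: int
    n_total: int
    rmse: float

    @property
    def outside_fraction(self) -> float:
        return self.n_outside / self.n_total if self.n_total else 0.0


def _predictive_bounds(cdf_vals: np.ndarray, level: float) -> int:
    """Smallest integer k with predictive CDF(k) >= level."""
    return int(np.searchsorted(cdf_vals, level, side="left"))


def validate(
    ensemble: PredictionEnsemble, held_out: pd.DataFrame
) -> ValidationReport:
    """Compare held-out trap records against the predictive distribution.

    Per record the predictive count is Poisson(lambda_draw * p_draw)
    mixed over the ensemble.  The 90% interval is central equal-tailed on
    the mixed CDF; an observation counts as outside only when strictly
    beyond both bounds.  RMSE is between observed counts and predictive
    means.
    """
    rec = validate_records(held_out)
    if len(rec) == 0:
        raise ValueError("held-out record table is empty")
    rids = rec["release_id"].unique()
    releases = pd.DataFrame(
        {
            "release_id": rids,
            "easting": ensemble.release.location[0],
            "northing": ensemble.release.location[1],
            "n_released": ensemble.release.n_released,
        }
    )
    compiled = CompiledLikelihood(
        rec, releases, ensemble.domain, ensemble.swarms, max_steps=ensemble.max_steps
    )
    n_rec = len(rec)
    n_draws = len(ensemble.draws)
    means = np.empty((n_draws, n_rec))
    for k, theta in enumerate(ensemble.draws):
        D, alpha, mu, sigma = theta[:4]
        unit = compiled._unit_lambda(D, alpha, sigma)
        p = theta[4:7][compiled.rec_type]
        means[k] = unit * compiled.rec_scale * np.exp(-mu * compiled.rec_time) * p

    pred_mean = means.mean(axis=0)
    y = compiled.rec_y
    kmax = int(np.ceil((means.max() + 10 * np.sqrt(means.max() + 1)))) + 1
    ks = np.arange(kmax + 1)
    lo = np.empty(n_rec, dtype=int)
    hi = np.empty(n_rec, dtype=int)
    med = np.empty(n_rec, dtype=int)
    for i in range(n_rec):
        cdf = stats.poisson.cdf(ks[:, None], means[:, i][None, :]).mean(axis=1)
        lo[i] = _predictive_bounds(cdf, 0.05)
        med[i] = _predictive_bounds(cdf, 0.50)
        hi[i] = _predictive_bounds(cdf, 0.95)
    outside = (y < lo) | (y > hi)
    rmse = float(np.sqrt(np.mean((y - pred_mean) ** 2)))
    table = rec.copy()
    table["pred_mean"] = pred_mean
    table["pred_median"] = med
    table["pred_q05"] = lo
    table["pred_q95"] = hi
    table["outside_90"] = outside
    return ValidationReport(
        table=table, n_outside=int(outside.sum()), n_total=n_rec, rmse=rmse
    )
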