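"""Posterior sampling by Delayed-Rejection Adaptive Metropolis (DRAM).

The posterior over the seven model parameters

    theta = (D, alpha, mu, sigma, p_ss, p_psc, p_cfr)

combines the Poisson-thinned trap likelihood (each evaluation solves the
dispersal PDE for the proposed process parameters) with the elicited
priors.  Random-walk Metropolis mixes poorly here and gradient-based
samplers would multiply the number of expensive PDE solves, so sampling
uses DRAM: a multivariate Gaussian proposal whose covariance adapts to
the chain history every ``adapt_every`` iterations, plus one
delayed-rejection stage — after a first-stage rejection a second, more
conservative proposal is drawn and accepted with the ratio that preserves
detailed balance.

Sampling operates on an unconstrained scale (log for the positive
parameters, logit for the catchabilities) with the appropriate Jacobian
corrections, which removes boundary rejections.

Two structural savings keep the likelihood affordable:

* the PDE is linear, so one unit-mass solve per *distinct release cell*
  serves every release from that cell (scaled by cohort size);
* mortality acts as an exact factor ``exp(-mu t)`` that commutes with
  diffusion and advection, so solves are done at ``mu = 0`` and cached on
  ``(D, alpha, sigma)`` only; mortality and catchability moves reuse them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, special

from .geometry import Domain, SwarmMap
from .observation import (
    Catchability,
    TRAP_TYPES,
    record_times,
    validate_records,
)
from .pde import CFLError, PDEParams, solve_unit_releases
from .priors import PARAM_NAMES, PriorSet, rate_to_daily_mortality

logger = logging.getLogger("dsmspread")

#: delayed-rejection second-stage covariance = first-stage / DR_SCALE
DR_SCALE = 4.0

#: adaptation scale 2.4^2 / dim (the canonical adaptive-Metropolis factor)
AM_SD = 2.4**2

#: regularisation added to the adapted covariance
AM_EPS = 1e-10

#: retry cap when drawing a finite starting point from the prior
INIT_RETRY_CAP = 200


# ---------------------------------------------------------------------------
# parameter transforms
# ---------------------------------------------------------------------------

class ParamTransform:
    """Elementwise log / logit / identity map to an unconstrained scale."""

    def __init__(self, kinds: tuple[str, ...]):
        for k in kinds:
            if k not in ("log", "logit", "identity"):
                raise ValueError(f"unknown transform kind {k!r}")
        self.kinds = tuple(kinds)
        self.dim = len(kinds)

    def forward(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        z = np.empty_like(theta)
        for i, k in enumerate(self.kinds):
            x = theta[..., i]
            if k == "log":
                z[..., i] = np.log(x)
            elif k == "logit":
                z[..., i] = special.logit(x)
            else:
                z[..., i] = x
        return z

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, float)
        theta = np.empty_like(z)
        for i, k in enumerate(self.kinds):
            if k == "log":
                theta[..., i] = np.exp(z[..., i])
            elif k == "logit":
                theta[..., i] = special.expit(z[..., i])
            else:
                theta[..., i] = z[..., i]
        return theta

    def log_jacobian(self, z: np.ndarray) -> float:
        """log |d theta / d z| — added to the transformed-scale target."""
        z = np.asarray(z, float)
        total = 0.0
        for i, k in enumerate(self.kinds):
            if k == "log":
                total += z[..., i]
            elif k == "logit":
                # d expit/dz = expit(z)(1-expit(z))
                total += -np.logaddexp(0, z[..., i]) - np.logaddexp(0, -z[..., i])
        return total


MODEL_TRANSFORM = ParamTransform(("log", "log", "log", "log", "logit", "logit", "logit"))


# ---------------------------------------------------------------------------
# compiled likelihood
# ---------------------------------------------------------------------------

class CompiledLikelihood:
    """Trap-record likelihood compiled to flat arrays for fast evaluation.

    Parameters
    ----------
    records
        Trap-catch table (see :mod:`dsmspread.observation`).
    releases
        One row per release: columns ``release_id, easting, northing,
        n_released``.
    domain, swarms
        Spatial context shared by all releases.
    max_steps
        Solver sub-step budget; parameter draws needing more are treated
        as numerically infeasible (log-likelihood ``-inf``).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        releases: pd.DataFrame,
        domain: Domain,
        swarms: SwarmMap | None,
        max_steps: int = 20_000,
        cache_size: int = 8,
    ):
        rec = validate_records(records)
        self.domain = domain
        self.swarms = swarms
        self.max_steps = max_steps
        self._cache: dict[tuple, np.ndarray] = {}
        self._cache_size = cache_size
        self.n_solves = 0  # diagnostic: PDE solves performed

        rel = releases.set_index("release_id")
        unknown = set(rec["release_id"]) - set(rel.index)
        if unknown:
            raise ValueError(f"records reference unknown releases: {sorted(unknown)}")

        # distinct release cells -> one unit solve each
        cells: list[tuple[int, int]] = []
        cell_of_release: dict[str, int] = {}
        scale_of_release: dict[str, float] = {}
        for rid, row in rel.iterrows():
            cell = domain.cell_index((row["easting"], row["northing"]))
            if cell not in cells:
                cells.append(cell)
            cell_of_release[rid] = cells.index(cell)
            scale_of_release[rid] = float(row["n_released"])
        self.cells = cells

        times = record_times(rec).to_numpy()
        self.times = np.unique(times)
        t_index = {t: k for k, t in enumerate(self.times)}

        n = len(rec)
        self.rec_cell = np.empty(n, dtype=int)
        self.rec_t = np.empty(n, dtype=int)
        self.rec_i = np.empty(n, dtype=int)
        self.rec_j = np.empty(n, dtype=int)
        self.rec_scale = np.empty(n)
        self.rec_type = np.empty(n, dtype=int)
        self.rec_y = rec["count"].to_numpy(float)
        self.rec_time = times
        for k, row in enumerate(rec.itertuples()):
            rid = row.release_id
            self.rec_cell[k] = cell_of_release[rid]
            self.rec_scale[k] = scale_of_release[rid]
            self.rec_t[k] = t_index[times[k]]
            try:
                i, j = domain.cell_index((row.easting, row.northing))
            except ValueError as err:
                raise ValueError(f"record row {row.Index}: {err}") from err
            self.rec_i[k] = i
            self.rec_j[k] = j
            self.rec_type[k] = TRAP_TYPES.index(row.trap_type)
        self._lgamma_y1 = special.gammaln(self.rec_y + 1.0)

    def _unit_lambda(self, D: float, alpha: float, sigma: float) -> np.ndarray:
        """Per-record unit-mass abundance (mortality-free), cached."""
        key = (round(float(D), 12), round(float(alpha), 12), round(float(sigma), 12))
        lam = self._cache.get(key)
        if lam is None:
            params = PDEParams(D=D, alpha=alpha, mu=0.0, sigma=sigma)
            fields = solve_unit_releases(
                self.cells, params, self.swarms, self.domain, self.times,
                max_steps=self.max_steps,
            )
            self.n_solves += 1
            lam = fields[self.rec_cell, self.rec_t, self.rec_i, self.rec_j]
            if len(self._cache) >= self._cache_size:
                self._cache.pop(next(iter(self._cache)))
            self._cache[key] = lam
        return lam

    def loglik(self, theta: np.ndarray) -> float:
        """Log-likelihood at a parameter vector in PARAM_NAMES order."""
        D, alpha, mu, sigma, p_ss, p_psc, p_cfr = map(float, theta)
        try:
            unit = self._unit_lambda(D, alpha, sigma)
        except CFLError:
            warnings.warn(
                "parameter draw requires more solver sub-steps than the "
                "budget allows; treating its likelihood as zero",
                RuntimeWarning,
                stacklevel=2,
            )
            return -np.inf
        p = np.array([p_ss, p_psc, p_cfr])[self.rec_type]
        mean = unit * self.rec_scale * np.exp(-mu * self.rec_time) * p
        y = self.rec_y
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = y * np.log(mean) - mean - self._lgamma_y1
        zero = mean <= 0
        if zero.any():
            lp = np.where(zero, np.where(y == 0, 0.0, -np.inf), lp)
        return float(lp.sum())


class LogPosterior:
    """Joint log posterior: compiled likelihood plus prior log density."""

    def __init__(self, compiled: CompiledLikelihood | None, priors: PriorSet):
        self.compiled = compiled
        self.priors = priors

    def __call__(self, theta: np.ndarray) -> float:
        theta = np.asarray(theta, float)
        if not np.all(np.isfinite(theta)):
            return -np.inf
        lp = self.priors.logpdf(theta)
        if not np.isfinite(lp):
            return -np.inf
        if self.compiled is not None:
            lp += self.compiled.loglik(theta)
        return lp


def log_posterior(
    theta,
    records: pd.DataFrame,
    releases: pd.DataFrame,
    domain: Domain,
    swarms: SwarmMap | None,
    priors: PriorSet,
) -> float:
    """One-shot joint log posterior (convenience wrapper; solves the PDE)."""
    if len(records) == 0:
        theta = np.asarray(theta, float)
        return priors.logpdf(theta) if np.all(np.isfinite(theta)) else -np.inf
    compiled = CompiledLikelihood(records, releases, domain, swarms)
    return LogPosterior(compiled, priors)(theta)


# ---------------------------------------------------------------------------
# DRAM sampler
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """Raw MCMC output: draws on the natural scale plus diagnostics."""

    draws: np.ndarray  # (n_chains, n_iter, dim)
    log_post: np.ndarray  # (n_chains, n_iter)
    accept_first: np.ndarray  # per chain
    accept_delayed: np.ndarray  # per chain
    cov_history: list  # per chain: list of (iteration, covariance)
    param_names: tuple[str, ...]
    burn_in: int

    def post_burn_in(self) -> np.ndarray:
        return self.draws[:, self.burn_in:, :]

    def flat(self) -> np.ndarray:
        return self.post_burn_in().reshape(-1, self.draws.shape[-1])

    def to_dataframe(self) -> pd.DataFrame:
        n_chains, n_iter, dim = self.draws.shape
        frames = []
        for c in range(n_chains):
            df = pd.DataFrame(self.draws[c], columns=list(self.param_names))
            df.insert(0, "iteration", np.arange(n_iter))
            df.insert(0, "chain", c)
            df["log_posterior"] = self.log_post[c]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, chol: np.ndarray) -> float:
    """Gaussian log density given a Cholesky factor of the covariance."""
    z = linalg.solve_triangular(chol, x - mean, lower=True)
    return -0.5 * z @ z - np.log(np.diag(chol)).sum() - 0.5 * len(z) * np.log(2 * np.pi)


def _log1m_exp(a: float) -> float:
    """log(1 - exp(a)) for a <= 0, -inf when a >= 0."""
    if a >= 0:
        return -np.inf
    if a > -0.693:
        return np.log(-np.expm1(a))
    return np.log1p(-np.exp(a))


def dram_sample(
    log_target,
    init: np.ndarray,
    cov0: np.ndarray,
    n_iter: int = 15_000,
    burn_in: int = 5_000,
    adapt_every: int = 200,
    dr_stages: int = 1,
    seed=None,
    param_names: tuple[str, ...] | None = None,
) -> ChainState:
    """Run DRAM chains against an arbitrary log target density.

    Parameters
    ----------
    log_target
        Callable mapping a parameter vector to a log density (may be
        ``-inf`` outside the support).
    init
        Starting points, shape ``(n_chains, dim)``; each must have finite
        target density.
    cov0
        Initial proposal covariance (dim x dim), shared across chains.
    n_iter, burn_in, adapt_every
        Chain length, burn-in length, and the interval at which the
        proposal covariance is re-estimated from the chain history
        (scaled by 2.4^2/dim with a small regularising ridge).
    dr_stages
        0 disables delayed rejection; 1 adds one second-stage proposal
        drawn from the first-stage covariance divided by 4, accepted with
        the ratio that preserves detailed balance.
    seed
        Master seed; per-chain streams are spawned deterministically.
    """
    init = np.atleast_2d(np.asarray(init, float))
    n_chains, dim = init.shape
    if not (0 <= burn_in < n_iter):
        raise ValueError("burn_in must be in [0, n_iter)")
    if param_names is None:
        param_names = tuple(f"p{i}" for i in range(dim))

    master = np.random.default_rng(seed)
    chain_rngs = master.spawn(n_chains)

    draws = np.empty((n_chains, n_iter, dim))
    log_post = np.empty((n_chains, n_iter))
    acc1 = np.zeros(n_chains, dtype=int)
    acc2 = np.zeros(n_chains, dtype=int)
    cov_history: list[list] = [[] for _ in range(n_chains)]

    for c in range(n_chains):
        rng = chain_rngs[c]
        x = init[c].copy()
        lx = float(log_target(x))
        if not np.isfinite(lx):
            raise ValueError(f"chain {c}: initial point has non-finite log target")
        cov = np.array(cov0, float)
        chol = np.linalg.cholesky(cov)
        # running moments for adaptation
        s1 = np.zeros(dim)
        s2 = np.zeros((dim, dim))
        n_hist = 0
        for it in range(n_iter):
            y = x + chol @ rng.standard_normal(dim)
            ly = float(log_target(y))
            log_a1_xy = min(0.0, ly - lx)
            if np.log(rng.random()) < log_a1_xy:
                x, lx = y, ly
                acc1[c] += 1
            elif dr_stages >= 1:
                # delayed rejection: conservative second-stage proposal
                chol2 = chol / np.sqrt(DR_SCALE)
                z = x + chol2 @ rng.standard_normal(dim)
                lz = float(log_target(z))
                if np.isfinite(lz):
                    # alpha2 = min(1, pi(z) q1(z,y) [1-a1(z,y)] /
                    #                 pi(x) q1(x,y) [1-a1(x,y)])
                    log_a1_zy = min(0.0, ly - lz)
                    num_1m = _log1m_exp(log_a1_zy)
                    den_1m = _log1m_exp(log_a1_xy)
                    if np.isfinite(num_1m):
                        lq_zy = _mvn_logpdf(y, z, chol)
                        lq_xy = _mvn_logpdf(y, x, chol)
                        log_a2 = (lz + lq_zy + num_1m) - (lx + lq_xy + den_1m)
                        if np.log(rng.random()) < min(0.0, log_a2):
                            x, lx = z, lz
                            acc2[c] += 1
            draws[c, it] = x
            log_post[c, it] = lx
            s1 += x
            s2 += np.outer(x, x)
            n_hist += 1
            if adapt_every and (it + 1) % adapt_every == 0 and n_hist > dim:
                mean = s1 / n_hist
                emp = (s2 - n_hist * np.outer(mean, mean)) / (n_hist - 1)
                cand = (AM_SD / dim) * emp + AM_EPS * np.eye(dim)
                try:
                    chol = np.linalg.cholesky(cand)
                    cov = cand
                    cov_history[c].append((it + 1, cov.copy()))
                except np.linalg.LinAlgError:
                    pass  # keep previous proposal if degenerate
    return ChainState(
        draws=draws,
        log_post=log_post,
        accept_first=acc1,
        accept_delayed=acc2,
        cov_history=cov_history,
        param_names=param_names,
        burn_in=burn_in,
    )


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rhat(chains: np.ndarray) -> np.ndarray:
    """Split-chain Gelman–Rubin R-hat per parameter.

    ``chains`` has shape ``(n_chains, n_draws, dim)`` (post burn-in).
    A parameter with zero within-chain variance yields NaN rather than an
    exception.
    """
    chains = np.asarray(chains, float)
    if chains.ndim == 2:
        chains = chains[..., None]
    n_chains, n_draws, dim = chains.shape
    if n_chains < 2 or n_draws < 10:
        raise ValueError("R-hat needs at least 2 chains of at least 10 draws")
    # split each chain in half
    half = n_draws // 2
    split = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = split.shape[0], half
    out = np.empty(dim)
    for k in range(dim):
        x = split[..., k]
        means = x.mean(axis=1)
        w = x.var(axis=1, ddof=1).mean()
        b = n * means.var(ddof=1)
        if w <= 0:
            out[k] = np.nan
            continue
        var_hat = (n - 1) / n * w + b / n
        out[k] = np.sqrt(var_hat / w)
    return out


def effective_sample_size(chains: np.ndarray) -> np.ndarray:
    """Bulk effective sample size per parameter (via arviz)."""
    import arviz as az

    chains = np.asarray(chains, float)
    if chains.ndim == 2:
        chains = chains[..., None]
    dim = chains.shape[-1]
    return np.array(
        [float(az.ess(az.convert_to_dataset(chains[..., k]))["x"]) for k in range(dim)]
    )


def summarize(state: ChainState, include_ess: bool = True) -> pd.DataFrame:
    """Posterior summary: mean, Q05, Q95, R-hat per parameter.

    The mortality rate additionally gets a ``mu_daily`` companion row —
    the equivalent daily mortality probability ``1 - exp(-mu)`` applied
    draw-wise, for comparison with studies reporting daily probabilities.
    """
    post = state.post_burn_in()
    flat = post.reshape(-1, post.shape[-1])
    rhat = gelman_rhat(post)
    ess = effective_sample_size(post) if include_ess else np.full(post.shape[-1], np.nan)
    rows = []
    for k, name in enumerate(state.param_names):
        x = flat[:, k]
        rows.append(
            {
                "parameter": name,
                "mean": x.mean(),
                "q05": np.quantile(x, 0.05),
                "q95": np.quantile(x, 0.95),
                "rhat": rhat[k],
                "ess": ess[k],
            }
        )
        if name == "mu":
            d = rate_to_daily_mortality(x)
            rows.append(
                {
                    "parameter": "mu_daily",
                    "mean": d.mean(),
                    "q05": np.quantile(d, 0.05),
                    "q95": np.quantile(d, 0.95),
                    "rhat": np.nan,
                    "ess": np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end fit
# ---------------------------------------------------------------------------

def _transformed_prior_cov(priors: PriorSet, transform: ParamTransform, rng) -> np.ndarray:
    """Diagonal covariance of prior draws on the unconstrained scale."""
    draws = priors.sample(rng, size=512)
    z = transform.forward(draws)
    v = np.var(z, axis=0)
    return np.diag(np.maximum(v, 1e-6))


def fit_mrr(
    records: pd.DataFrame,
    releases: pd.DataFrame,
    domain: Domain,
    swarms: SwarmMap | None,
    priors: PriorSet,
    n_chains: int = 3,
    n_iter: int = 15_000,
    burn_in: int = 5_000,
    adapt_every: int = 200,
    seed=None,
    max_steps: int = 20_000,
) -> ChainState:
    """Fit the full model to a trap-catch table with DRAM.

    Returns chains on the natural parameter scale in PARAM_NAMES order.
    Initial points are drawn from the prior (re-drawn while the posterior
    is non-finite, up to a retry cap); the initial proposal covariance is
    one tenth of the diagonal prior covariance on the transformed scale.
    """
    compiled = CompiledLikelihood(records, releases, domain, swarms, max_steps=max_steps)
    post_nat = LogPosterior(compiled, priors)
    transform = MODEL_TRANSFORM

    def log_target(z: np.ndarray) -> float:
        theta = transform.inverse(z)
        lp = post_nat(theta)
        if not np.isfinite(lp):
            return -np.inf
        return lp + transform.log_jacobian(z)

    master = np.random.default_rng(seed)
    init = np.empty((n_chains, transform.dim))
    for c in range(n_chains):
        for attempt in range(INIT_RETRY_CAP):
            theta0 = priors.sample(master)
            z0 = transform.forward(theta0)
            if np.isfinite(log_target(z0)):
                init[c] = z0
                break
        else:
            raise RuntimeError(
                "could not find a finite-posterior starting point from the prior"
            )
    cov0 = 0.1 * _transformed_prior_cov(priors, transform, master)

    state_z = dram_sample(
        log_target,
        init,
        cov0,
        n_iter=n_iter,
        burn_in=burn_in,
        adapt_every=adapt_every,
        dr_stages=1,
        seed=master,
        param_names=PARAM_NAMES,
    )
    logger.info(
        "DRAM finished: %d PDE solves, first-stage acceptance %s, delayed %s",
        compiled.n_solves,
        (state_z.accept_first / n_iter).round(3).tolist(),
        (state_z.accept_delayed / n_iter).round(3).tolist(),
    )
    # map draws back to the natural scale
    nat = transform.inverse(state_z.draws.reshape(-1, transform.dim)).reshape(
        state_z.draws.shape
    )
    return ChainState(
        draws=nat,
        log_post=state_z.log_post,
        accept_first=state_z.accept_first,
        accept_delayed=state_z.accept_delayed,
        cov_history=state_z.cov_history,
        param_names=PARAM_NAMES,
        burn_in=burn_in,
    )
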