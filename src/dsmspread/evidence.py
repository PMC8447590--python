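"""Per-expert model evidence, Bayes factors, and pooled DSM priors.

Each expert's elicited (mortality, dispersal) prior pair is treated as an
alternative model for the wild-type MRR data; the shared chemotaxis and
catchability priors are common to all of them.  The marginal likelihood
of each expert-model is estimated by prior-predictive Monte Carlo:

    Z_k = E_{theta ~ prior_k} [ L(y | theta) ]
        ~ (1/n) sum_i L(y | theta_i),     theta_i ~ prior_k,

stabilised with log-sum-exp, with a Monte Carlo standard error from
batching.  Under equal prior model probabilities the posterior model
weights are proportional to the evidences; experts whose wild-type priors
anticipate the data best therefore dominate the weighted linear pool of
their *DSM* priors, which is the predictive prior used for the modified
strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .geometry import Domain, SwarmMap
from .inference import CompiledLikelihood
from .priors import (
    ExpertPrior,
    Mixture,
    PriorSet,
    pool_priors,
    rate_to_daily_mortality,
)


@dataclass
class EvidenceReport:
    """Evidence, Bayes factors and model weights for a set of experts."""

    expert_ids: list[str]
    log_evidence: np.ndarray
    mc_error: np.ndarray
    weights: np.ndarray

    @property
    def bayes_factors(self) -> np.ndarray:
        """BF of each expert against the best one (best = 1)."""
        best = np.nanmax(self.log_evidence)
        return np.exp(self.log_evidence - best)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expert_id": self.expert_ids,
                "log_evidence": self.log_evidence,
                "mc_error": self.mc_error,
                "bayes_factor": self.bayes_factors,
                "weight": self.weights,
            }
        )


def _expert_prior_set(expert: ExpertPrior, shared: PriorSet) -> PriorSet:
    """Single-expert prior set: the expert's (mu, D), everything else shared."""
    return PriorSet(
        mu=expert.mortality_prior(),
        D=expert.diffusion_prior(),
        alpha=shared.alpha,
        sigma=shared.sigma,
        catchability=dict(shared.catchability),
    )


def monte_carlo_log_evidence(
    sample_prior,
    loglik,
    n_draws: int,
    seed=None,
    n_batches: int = 10,
) -> tuple[float, float]:
    """Core prior-predictive Monte Carlo estimator.

    ``sample_prior(rng, size)`` draws parameter vectors; ``loglik(theta)``
    returns the log-likelihood of the data (``-inf`` allowed).  Returns
    ``(log_evidence, mc_error)`` with the error taken as the standard
    error over ``n_batches`` equal batches on the log scale.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    thetas = np.atleast_2d(sample_prior(rng, n_draws))
    ll = np.array([float(loglik(t)) for t in thetas])
    if np.all(np.isneginf(ll)):
        return -np.inf, np.nan
    logz = float(logsumexp(ll) - np.log(n_draws))
    batch = n_draws // n_batches
    logz_b = np.array(
        [
            logsumexp(ll[b * batch : (b + 1) * batch]) - np.log(batch)
            for b in range(n_batches)
        ]
    )
    finite = np.isfinite(logz_b)
    if finite.sum() >= 2:
        mc_err = float(np.std(logz_b[finite], ddof=1) / np.sqrt(finite.sum()))
    else:
        mc_err = np.nan
    return logz, mc_err


def log_evidence(
    expert: ExpertPrior,
    shared: PriorSet,
    records: pd.DataFrame,
    releases: pd.DataFrame,
    domain: Domain,
    swarms: SwarmMap | None,
    n_draws: int = 1000,
    seed=None,
    n_batches: int = 10,
    max_steps: int = 20_000,
) -> tuple[float, float]:
    """Prior-predictive Monte Carlo estimate of one expert's log evidence.

    Returns ``(log_evidence, mc_error)``; the error is the standard error
    over ``n_batches`` equal batches of draws, propagated on the log scale.
    With no records the likelihood is identically 1 and the log evidence
    is exactly 0.  Draws whose parameters exceed the solver's sub-step
    budget contribute zero likelihood (their evidence share is negligible
    in the regimes of interest).
    """
    if len(records) == 0:
        if n_draws < 100:
            raise ValueError("n_draws must be at least 100 for a stable estimate")
        return 0.0, 0.0
    prior = _expert_prior_set(expert, shared)
    compiled = CompiledLikelihood(records, releases, domain, swarms, max_steps=max_steps)

    def _ll(theta):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return compiled.loglik(theta)

    logz, mc_err = monte_carlo_log_evidence(
        prior.sample, _ll, n_draws, seed=seed, n_batches=n_batches
    )
    if np.isneginf(logz):
        warnings.warn(
            f"all {n_draws} prior draws for expert {expert.expert_id!r} have "
            "zero likelihood; evidence reported as -inf",
            RuntimeWarning,
            stacklevel=2,
        )
    return logz, mc_err


def bma_weights(log_evidences) -> np.ndarray:
    """Posterior model weights under equal prior model probabilities.

    ``-inf`` entries receive weight exactly 0; the weights are invariant
    to adding a constant to every log evidence.
    """
    le = np.asarray(log_evidences, float)
    if np.any(np.isnan(le)) or np.any(np.isposinf(le)):
        raise ValueError("log evidences must be finite or -inf")
    if np.all(np.isneginf(le)):
        raise ValueError("all experts have zero evidence; weights undefined")
    shifted = le - np.max(le[np.isfinite(le)])
    w = np.exp(shifted)
    w[np.isneginf(le)] = 0.0
    return w / w.sum()


def compute_evidence_report(
    experts: list[ExpertPrior],
    shared: PriorSet,
    records: pd.DataFrame,
    releases: pd.DataFrame,
    domain: Domain,
    swarms: SwarmMap | None,
    n_draws: int = 1000,
    seed=None,
    **kwargs,
) -> EvidenceReport:
    """Evidence and BMA weights for every expert against the same data."""
    if not experts:
        raise ValueError("at least one expert is required")
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=len(experts))
    le, err = [], []
    for expert, s in zip(experts, seeds):
        z, e = log_evidence(
            expert, shared, records, releases, domain, swarms,
            n_draws=n_draws, seed=int(s), **kwargs,
        )
        le.append(z)
        err.append(e)
    le = np.array(le)
    return EvidenceReport(
        expert_ids=[e.expert_id for e in experts],
        log_evidence=le,
        mc_error=np.array(err),
        weights=bma_weights(le),
    )


def pooled_dsm_prior(
    experts_dsm: list[ExpertPrior], weights
) -> tuple[Mixture, Mixture]:
    """Weighted linear pool of the experts' DSM mortality and diffusion priors.

    ``weights`` are the BMA weights earned on the wild-type data.  Returns
    ``(mu_pool, D_pool)`` mixtures; dispersal priors are pushed through
    the ``D = d^2/pi`` transform before pooling.
    """
    if not experts_dsm:
        raise ValueError("at least one DSM expert prior is required")
    for e in experts_dsm:
        if e.strain != "DSM":
            raise ValueError(
                f"expert {e.expert_id!r} has strain {e.strain!r}; DSM required"
            )
    w = np.asarray(weights, float)
    mu_pool = pool_priors([e.mortality_prior() for e in experts_dsm], w)
    d_pool = pool_priors([e.diffusion_prior() for e in experts_dsm], w)
    return mu_pool, d_pool


def pooled_prior_summary(mu_pool: Mixture, d_pool: Mixture) -> pd.DataFrame:
    """Summary table of the pooled DSM priors: mean, Q05, Q95.

    The mortality row carries a companion ``mu_daily`` row with the
    equivalent daily mortality probability ``1 - exp(-mu)`` applied to
    each summary entry, the convention used when comparing rates across
    studies.
    """
    rows = []
    for name, dist in (("mu", mu_pool), ("D", d_pool)):
        rows.append(
            {
                "parameter": name,
                "mean": dist.mean(),
                "q05": dist.ppf(0.05),
                "q95": dist.ppf(0.95),
            }
        )
        if name == "mu":
            rows.append(
                {
                    "parameter": "mu_daily",
                    "mean": rate_to_daily_mortality(rows[-1]["mean"]),
                    "q05": rate_to_daily_mortality(rows[-1]["q05"]),
                    "q95": rate_to_daily_mortality(rows[-1]["q95"]),
                }
            )
    return pd.DataFrame(rows)
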