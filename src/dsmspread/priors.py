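"""Expert priors, elicitation transforms, and the shared prior set.

Expert knowledge enters the model on two natural scales: the daily
probability of survival ``p`` of a released male, and the mean daily
dispersal distance ``d`` (metres).  The model itself is parameterised by a
mortality *rate* ``mu`` (1/day) and a diffusion coefficient ``D``
(m^2/day), so elicited distributions are pushed through

    mu = -log(p)          and          D = d^2 / (pi * t),

the second with a standardised time frame of t = 1 day.  The dispersal
relation comes from the mean displacement of a 2-D Brownian motion,
``E|r| = sqrt(pi * D * t)``, inverted for ``D``.

Shared (strain-independent) priors follow the study's prior table:
log-normal(-2, 1) for the chemotaxis strength ``alpha`` (spanning roughly
1% to 140% of the attraction at the source), log-normal(3.5, 4) for the
attraction range ``sigma``, and Beta priors on the three trap
catchabilities — Beta(10, 20) for swarm sampling (a third of the swarm is
captured on average, per the field standard operating procedure),
Beta(1.4, 1) for pyrethroid spray catches (compounds average 1.4 rooms)
and Beta(1, 1) for clay-pot resting catches.

Note: the configured log-scale SD of 4 for ``sigma`` is extremely diffuse
(its 99th percentile exceeds 10^5 m, far above the 3–40 m literature range
for swarm attraction); it is kept as the documented default but can be
overridden through the prior config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

#: canonical parameter order used by inference and prediction
PARAM_NAMES = ("D", "alpha", "mu", "sigma", "p_ss", "p_psc", "p_cfr")

TRAP_TYPES = ("ss", "psc", "cfr")


# ---------------------------------------------------------------------------
# scalar transforms
# ---------------------------------------------------------------------------

def survival_to_rate(p: float) -> float:
    """Mortality rate mu = -log(p) from a daily survival probability."""
    p = float(p)
    if not (0.0 < p <= 1.0):
        raise ValueError(f"daily survival probability must be in (0, 1], got {p}")
    return -np.log(p)


def rate_to_daily_mortality(mu) -> float | np.ndarray:
    """Daily mortality probability 1 - exp(-mu) from a rate mu >= 0."""
    mu = np.asarray(mu, float)
    if np.any(mu < 0):
        raise ValueError("mortality rate must be non-negative")
    out = -np.expm1(-mu)
    return float(out) if out.ndim == 0 else out


def dispersal_to_diffusion(d: float, t: float = 1.0) -> float:
    """Diffusion coefficient D = d^2 / (pi * t) from mean daily dispersal d (m)."""
    if d < 0:
        raise ValueError("dispersal distance must be non-negative")
    if t <= 0:
        raise ValueError("time frame must be positive")
    return d * d / (np.pi * t)


# ---------------------------------------------------------------------------
# distribution wrappers
# ---------------------------------------------------------------------------

class Prior:
    """A named scipy distribution family with hyperparameters.

    Families: ``lognormal`` (location, scale on the log scale), ``beta``
    (a, b), ``gamma`` (shape, scale), ``uniform`` (low, high), ``normal``
    (mean, sd).
    """

    _FAMILIES = ("lognormal", "beta", "gamma", "uniform", "normal")

    def __init__(self, family: str, params: tuple):
        family = family.lower()
        if family not in self._FAMILIES:
            raise ValueError(
                f"unknown distribution family {family!r}; known: {self._FAMILIES}"
            )
        self.family = family
        self.params = tuple(float(p) for p in params)
        a, b = self.params
        if family == "lognormal":
            self._rv = stats.lognorm(s=b, scale=np.exp(a))
        elif family == "beta":
            self._rv = stats.beta(a, b)
        elif family == "gamma":
            self._rv = stats.gamma(a, scale=b)
        elif family == "uniform":
            self._rv = stats.uniform(loc=a, scale=b - a)
        else:
            self._rv = stats.norm(loc=a, scale=b)

    def pdf(self, x):
        return self._rv.pdf(x)

    def logpdf(self, x):
        return self._rv.logpdf(x)

    def cdf(self, x):
        return self._rv.cdf(x)

    def ppf(self, q):
        return self._rv.ppf(q)

    def mean(self) -> float:
        return float(self._rv.mean())

    def var(self) -> float:
        return float(self._rv.var())

    def rvs(self, size=None, rng=None):
        return self._rv.rvs(size=size, random_state=rng)

    def support(self) -> tuple[float, float]:
        return tuple(map(float, self._rv.support()))

    def to_dict(self) -> dict:
        return {"family": self.family, "params": list(self.params)}

    @classmethod
    def from_dict(cls, d: dict) -> "Prior":
        return cls(d["family"], tuple(d["params"]))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Prior({self.family!r}, {self.params})"


class MortalityRatePrior:
    """Prior on mu = -log(p) induced by a Beta(a, b) prior on survival p.

    All quantities are exact: the density follows from the monotone change
    of variables, and the mean/variance use digamma/trigamma identities for
    E[-log p] under a Beta law.
    """

    def __init__(self, survival: Prior):
        if survival.family != "beta":
            raise ValueError("survival prior must be a beta distribution")
        self._p = survival
        self.a, self.b = survival.params

    def pdf(self, mu):
        mu = np.asarray(mu, float)
        p = np.exp(-mu)
        out = np.where(mu >= 0, self._p.pdf(p) * p, 0.0)
        return float(out) if out.ndim == 0 else out

    def logpdf(self, mu):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(mu))

    def cdf(self, mu):
        mu = np.asarray(mu, float)
        out = np.where(mu >= 0, 1.0 - self._p.cdf(np.exp(-mu)), 0.0)
        return float(out) if out.ndim == 0 else out

    def ppf(self, q):
        q = np.asarray(q, float)
        out = -np.log(self._p.ppf(1.0 - q))
        return float(out) if out.ndim == 0 else out

    def mean(self) -> float:
        return float(special.digamma(self.a + self.b) - special.digamma(self.a))

    def var(self) -> float:
        return float(special.polygamma(1, self.a) - special.polygamma(1, self.a + self.b))

    def rvs(self, size=None, rng=None):
        return -np.log(self._p.rvs(size=size, rng=rng))

    def support(self) -> tuple[float, float]:
        return (0.0, np.inf)

    def to_dict(self) -> dict:
        return {"family": "mortality_from_beta_survival", "params": [self.a, self.b]}


class Mixture:
    """Finite mixture (linear opinion pool) of component distributions."""

    def __init__(self, components: list, weights):
        if len(components) == 0:
            raise ValueError("mixture needs at least one component")
        w = np.asarray(weights, float)
        if w.shape != (len(components),):
            raise ValueError("one weight per component required")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
        self.components = list(components)
        self.weights = w / w.sum()

    def pdf(self, x):
        x = np.asarray(x, float)
        return sum(w * c.pdf(x) for w, c in zip(self.weights, self.components))

    def logpdf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pdf(x))

    def cdf(self, x):
        x = np.asarray(x, float)
        return sum(w * c.cdf(x) for w, c in zip(self.weights, self.components))

    def mean(self) -> float:
        return float(sum(w * c.mean() for w, c in zip(self.weights, self.components)))

    def ppf(self, q):
        scalar = np.isscalar(q)
        qs = np.atleast_1d(np.asarray(q, float))
        if np.any((qs <= 0) | (qs >= 1)):
            raise ValueError("quantile levels must be in (0, 1)")
        out = np.empty_like(qs)
        for k, qq in enumerate(qs):
            los, his = zip(*((c.ppf(1e-12), c.ppf(1 - 1e-12)) for c in self.components))
            lo, hi = min(los), max(his)
            out[k] = optimize.brentq(lambda x: self.cdf(x) - qq, lo, hi, xtol=1e-12)
        return float(out[0]) if scalar else out

    def rvs(self, size=None, rng=None):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        n = 1 if size is None else int(np.prod(size))
        ks = rng.choice(len(self.components), size=n, p=self.weights)
        draws = np.empty(n)
        for k in range(len(self.components)):
            m = ks == k
            if m.any():
                draws[m] = np.asarray(self.components[k].rvs(size=int(m.sum()), rng=rng))
        if size is None:
            return float(draws[0])
        return draws.reshape(size)

    def support(self) -> tuple[float, float]:
        los, his = zip(*(c.support() for c in self.components))
        return (min(los), max(his))


def prior_quantile(dist, q: float) -> float:
    """Exact quantile of a prior distribution at level q in (0, 1)."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile level must be in (0, 1), got {q}")
    return float(dist.ppf(q))


def pool_priors(components: list, weights=None) -> Mixture:
    """Weighted linear opinion pool of expert distributions.

    Defaults to uniform weights.  The pooled density is the weighted sum
    of component densities; the pooled mean is the weight-weighted sum of
    component means.
    """
    if len(components) == 0:
        raise ValueError("cannot pool an empty set of priors")
    if weights is None:
        weights = np.full(len(components), 1.0 / len(components))
    return Mixture(components, weights)


# ---------------------------------------------------------------------------
# expert priors and the shared prior set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpertPrior:
    """One expert's elicited beliefs for one strain.

    ``survival_dist`` is a Beta prior on the daily survival probability;
    ``dispersal_dist`` a log-normal prior on mean daily dispersal distance
    (m) — the family every expert in the study settled on.
    """

    expert_id: str
    strain: str  # "WT" or "DSM"
    survival_dist: Prior
    dispersal_dist: Prior

    def __post_init__(self) -> None:
        if self.strain not in ("WT", "DSM"):
            raise ValueError(f"strain must be 'WT' or 'DSM', got {self.strain!r}")
        lo, hi = self.survival_dist.support()
        if lo < 0 or hi > 1:
            raise ValueError("survival prior support must lie within (0, 1)")
        if self.dispersal_dist.support()[0] < 0:
            raise ValueError("dispersal prior support must be non-negative")

    def mortality_prior(self) -> MortalityRatePrior:
        """Induced prior on the mortality rate mu = -log(p)."""
        return MortalityRatePrior(self.survival_dist)

    def diffusion_prior(self, t: float = 1.0) -> Prior:
        """Induced prior on D = d^2/(pi t).

        For a log-normal dispersal prior with log-scale (m, s) this is the
        log-normal with log-scale (2m - log(pi t), 2s), exactly.
        """
        if self.dispersal_dist.family != "lognormal":
            raise ValueError("diffusion transform requires a log-normal dispersal prior")
        m, s = self.dispersal_dist.params
        return Prior("lognormal", (2.0 * m - np.log(np.pi * t), 2.0 * s))


@dataclass
class PriorSet:
    """The complete prior over the 7 model parameters, plus the expert pool.

    ``mu`` and ``D`` typically come from the expert pool (mixtures over
    experts); ``alpha``, ``sigma`` and the catchabilities are shared,
    strain-independent priors.
    """

    mu: object
    D: object
    alpha: Prior = field(default_factory=lambda: Prior("lognormal", (-2.0, 1.0)))
    sigma: Prior = field(default_factory=lambda: Prior("lognormal", (3.5, 4.0)))
    catchability: dict = field(
        default_factory=lambda: {
            "ss": Prior("beta", (10.0, 20.0)),
            "psc": Prior("beta", (1.4, 1.0)),
            "cfr": Prior("beta", (1.0, 1.0)),
        }
    )
    expert_pool: list = field(default_factory=list)
    expert_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.expert_pool and self.expert_weights is None:
            k = len(self.expert_pool)
            self.expert_weights = np.full(k, 1.0 / k)
        if self.expert_weights is not None:
            w = np.asarray(self.expert_weights, float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("expert weights must form a simplex")
            self.expert_weights = w
        for t in TRAP_TYPES:
            if t not in self.catchability:
                raise ValueError(f"missing catchability prior for trap type {t!r}")

    @classmethod
    def from_experts(
        cls, experts: list[ExpertPrior], weights=None, **shared
    ) -> "PriorSet":
        """Assemble the prior set with mu and D pooled over the experts."""
        if not experts:
            raise ValueError("at least one expert prior is required")
        if weights is None:
            weights = np.full(len(experts), 1.0 / len(experts))
        mu = pool_priors([e.mortality_prior() for e in experts], weights)
        D = pool_priors([e.diffusion_prior() for e in experts], weights)
        return cls(mu=mu, D=D, expert_pool=list(experts),
                   expert_weights=np.asarray(weights, float), **shared)

    def _marginals(self) -> list:
        return [
            self.D,
            self.alpha,
            self.mu,
            self.sigma,
            self.catchability["ss"],
            self.catchability["psc"],
            self.catchability["cfr"],
        ]

    def logpdf(self, theta: np.ndarray) -> float:
        """Joint log prior density at a parameter vector in PARAM_NAMES order."""
        theta = np.asarray(theta, float)
        total = 0.0
        for dist, x in zip(self._marginals(), theta):
            lp = float(dist.logpdf(x))
            if not np.isfinite(lp):
                return -np.inf
            total += lp
        return total

    def sample(self, rng, size: int | None = None) -> np.ndarray:
        """Draw parameter vectors (PARAM_NAMES order) from the prior."""
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        n = 1 if size is None else size
        draws = np.column_stack(
            [np.atleast_1d(np.asarray(d.rvs(size=n, rng=rng))) for d in self._marginals()]
        )
        return draws[0] if size is None else draws

    def marginal(self, name: str):
        """The prior marginal for a named parameter."""
        if name not in PARAM_NAMES:
            raise KeyError(name)
        return self._marginals()[PARAM_NAMES.index(name)]
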