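# Methods

## Process model

Released sterile males are assumed to move by isotropic diffusion,
modulated by chemotaxis toward mating swarms, and to die at a constant
rate. The expected abundance per areal unit λ(s, t) solves

    ∂λ/∂t = D [ ∇²λ − α ∇·(λ ∇U) ] − μ λ

on a raster of 10 m × 10 m cells (one areal unit = 100 m²) with zero-flux
(reflecting) boundaries. The attraction surface is a squared-exponential
sum over swarm sites, U(s) = Σ_ℓ exp(−|s − s_ℓ|²/σ²). Two modelling
conventions deserve note:

* **Advection velocity.** The diffusion coefficient multiplies the whole
  bracketed term, so the advective velocity is v = D·α·∇U and the
  advective speed scales with D. This coupling is retained as the model's
  convention; sensitivity to it can be probed by rescaling α.
* **Units of α.** U is dimensionless here; the per-"reward" unit of α is
  absorbed into its scale, which the weakly informative prior spans over
  several orders of magnitude.

There is no birth term (the males are sterile), no wind, and no
interaction between individuals; the attraction field does not saturate
with mosquito density. The model is linear in λ, which the implementation
exploits: one unit-mass solve per distinct release cell serves every
release from that cell, and mortality is applied as the exact factor
e^{−μt}, so PDE solves are cached on (D, α, σ) alone.

### Numerics

Finite volumes with operator splitting per sub-step: (i) diffusion by the
5-point Laplacian in flux form (zero boundary flux, identical to mirrored
ghost cells and exactly conservative); (ii) advection by first-order
upwind fluxes with face velocities from one-sided differences of U (zero
advective flux through the walls); (iii) mortality as an exact pointwise
decay. The time step is 0.9·min(h²/4D, h/max(|vx|+|vy|)) capped at 0.05
day, which preserves positivity. Consequently total mass satisfies
N(t) = N₀e^{−μt} to machine precision for any (D, α, σ) — the solver's
primary oracle — and the free-diffusion solution converges to the heat
kernel at second order in h. A user-supplied step larger than the
stability bound is refused with the admissible step reported.

Parameter draws whose stability-bound step would require more sub-steps
than a configurable budget (`max_steps`) are treated as numerically
infeasible: the likelihood returns −∞ with a warning rather than
crashing. On a 10 m grid with a 7-day horizon this budget (default
20 000; tighter budgets can be chosen for Monte Carlo work) corresponds
to diffusion coefficients of order 10⁴–10⁵ m²/day, far beyond the regime
the trap data can inform. In evidence estimation such prior draws
contribute zero weight — an explicit, conservative approximation.

The inner sub-step kernel is JIT-compiled with numba when available; a
pure-numpy implementation of the identical scheme is the reference path
and is used automatically otherwise.

## Observation model

The latent number of marked males in a trap's cell at sampling time is
Poisson(λ); the trap thins it binomially with a type-specific
catchability. The marginal count is Poisson(λ·p_c) — the infinite sum
over latent outcomes collapses analytically, and the literal truncated
sum is kept in the test suite as an oracle. Catchability is defined at
the 10 m raster resolution ("the trap sees its cell"), so predictions
must use the same resolution as the fit. Captured mosquitoes are not
removed from λ (no depletion term; recaptures are a small fraction of
each cohort), and identification errors are taken as zero.

Within-day sampling times are fixed at window midpoints of the field
protocol: release at 16:00 (t = 0), swarm sampling at 20:00 nightly
(t = k + 4/24 days), spray and clay-pot collections at 06:30 each
following morning (t = (k−1) + 14.5/24). Whether swarm sampling happened
every evening is not recorded; the simulator samples nightly.

## Priors and elicitation transforms

Experts express beliefs on the daily survival probability p (Beta) and
the mean daily dispersal distance d in metres (log-normal, the family all
experts preferred). These map to model parameters by μ = −log p and
D = d²/(π t) with t = 1 day; the latter inverts the mean displacement
E|r| = √(πDt) of 2-D Brownian motion. Both transforms have exact
pushforwards: a Beta survival prior induces a mortality prior with
digamma/trigamma moments, and a log-normal dispersal prior induces a
log-normal diffusion prior with doubled log-scale.

Shared priors: α ~ log-normal(−2, 1) (spanning ~1% to ~140% of the
source attraction between its 1st and 99th percentiles — the exact 99th
percentile is 138.6%), σ ~ log-normal(3.5, 4), and Beta catchabilities
(10, 20) for swarm sampling (a third of the swarm is captured on
average), (1.4, 1) for spray catches (compounds average 1.4 rooms), and
(1, 1) for clay pots. The σ prior's log-scale SD of 4 is kept as
configured but flagged: it places substantial mass far above the 3–40 m
range reported for swarm attraction, and with small datasets σ's
posterior remains essentially prior-dominated (visible as low effective
sample sizes in short demonstration runs).

The per-expert hyperparameters of the original elicitation are not
published. `synthetic_expert_pool()` is a clearly labelled synthetic
stand-in with four wild-type and four modified-strain experts reproducing
the qualitative regimes (high WT survival, dispersal beliefs well above
what recapture data support; much higher DSM mortality and very diffuse
DSM dispersal).

## Inference

Sampling uses Delayed-Rejection Adaptive Metropolis on an unconstrained
scale (log for D, α, μ, σ; logit for the catchabilities) with Jacobian
corrections. Defaults mirror the analysis design: 3 chains × 15 000
iterations, 5 000 burn-in, proposal covariance re-estimated every 200
iterations as (2.4²/dim)·cov(history) + 10⁻¹⁰ I, one delayed-rejection
stage with second-stage covariance equal to the first-stage divided by 4
and the acceptance ratio that preserves detailed balance (verified on a
discrete analogue). Initial points are drawn from the prior (re-drawn
while the posterior is non-finite, up to a cap); the initial proposal
covariance is a tenth of the diagonal prior covariance on the transformed
scale. Convergence is monitored with classic split-chain R̂ (cross-checked
against arviz's split implementation in the tests); effective sample
sizes come from arviz. Summaries report the mean and the 5%/95%
quantiles, with a `mu_daily` companion row applying 1 − e^{−μ} draw-wise
— quantiles commute with the monotone transform, means deliberately do
not.

## Evidence weighting and pooling

Each expert's (mortality, dispersal) prior pair is one model; the shared
α, σ and catchability priors are common to all. Log evidence is estimated
by prior-predictive Monte Carlo (log-sum-exp stabilised) with a standard
error from batching; the estimator is validated against the closed-form
Poisson–gamma marginal. Posterior model weights assume equal prior model
probabilities; −∞ evidences receive weight exactly zero. The experts'
modified-strain priors are then pooled as a weighted linear mixture
(pooled density = Σ w_k f_k), with dispersal pushed through the diffusion
transform before pooling. Evidence is computed jointly over all fitting
campaigns.

## Prediction

An ensemble of parameter draws (thinned posterior chains, a pooled prior,
or a fixed vector; 500 draws by default) is propagated through the PDE
for a release scenario (5 000 males at one location by default, 60-day
horizon):

* **Persistence** — expected total abundance per day per draw; the day
  the expected count crosses a threshold (1 by default) is interpolated
  linearly on the log scale (the decay is exponential, so the curve is a
  straight line there); draws that never cross are right-censored at the
  horizon. Thresholding uses the expected field, not realised counts.
* **Absence radius** — under the Poisson field, P(zero beyond r) =
  E_draws[exp(−Σ_{dist>r} λ)]. Candidate radii are cell-centre distances
  from the release point, capped at the distance to the nearest domain
  edge: beyond that a full disk is not contained in the domain and
  absence cannot be certified, which the result flags.
* **Expected extent** — cells whose mean-over-draws expected count is at
  least 1, polygonised; the mean field is thresholded (not per-draw
  masks), while the absence radius averages the zero-probability over
  draws.
* **Validation** — per held-out trap-day, the predictive count mixes
  Poisson(λ·p) over draws; 90% intervals are central equal-tailed on the
  mixed CDF with boundary ties counted as inside, and the RMSE compares
  observed counts with predictive means.

Because counts are integers, the exact probability of falling outside a
90% central interval is at most 10% and can be much lower at small means;
calibration tests therefore compare the observed outside-fraction with
the exact Poisson outside-rate (within binomial noise) and check that the
rate never exceeds the nominal level, rather than asserting an exact 10%.

## Synthetic data

The campaign generator reproduces the published design exactly where it
is printed — three release sites at the published GPS coordinates
(projected to local planar metres by an equirectangular projection,
sub-metre accurate at village scale), the twelve fitting cohorts of
655–2107 males, 5 recapture days for the first campaign and 7 for the
others, and a held-out validation release of 5992 — and invents what is
not: compound and swarm-site layouts (clustered around the release sites,
seeded) and trap counts (10 swarm-sampling, 20 spray, 20 clay-pot traps,
all within 500 m of the sites by construction). Default generating
parameters sit in the regime the wild-type data support: D = 130 m²/day,
α = 0.07, μ = 0.15/day, σ = 30 m, p_ss = 0.29, p_psc = 0.18,
p_cfr = 0.03. These are fixture settings for testing the machinery, not
claims about the field system. Per-release RNG streams are spawned from
one master seed so regenerating a single campaign leaves the others
untouched.

What the synthetic data do not emulate: real village geometry, weather
and seasonality, trap interference, marking loss, or identification
error. Passing recovery and calibration tests therefore demonstrates
that the inference machinery is self-consistent — data generated by the
model are correctly inverted — not that the model is adequate for any
particular field site.

## Problem sizes used in the test suite

Tests run the same algorithms at reduced scale, chosen as sizes at which
the checked properties are already decisive: parameter recovery uses 3
replicate campaigns with 3 chains × 1 200 iterations (burn-in 400) on a
~60 × 52 grid and a likelihood step budget of 4 000 sub-steps; evidence
ranking uses 10 simulated campaigns × 150 prior draws; predictive
calibration uses ~400 held-out trap-days; the heat-kernel comparison uses
D = 150 m²/day over 60 days on a 150 × 150 grid, where the 10 m
discretisation resolves the kernel's 10⁻⁶ tail to better than 2%.

## Known limitations

* First-order upwind advection is diffusive; with strong chemotaxis
  (large α·D) swarm-site peaks are smeared relative to higher-order
  schemes. The parameter regime identified by MRR data keeps advective
  CFL numbers small.
* The explicit scheme's step scales like 1/D, so the very diffuse pooled
  DSM dispersal prior (D up to 10⁵–10⁶ m²/day) is expensive or infeasible
  on a 10 m grid; coarser rasters (with correspondingly reinterpreted
  catchabilities) or the analytic mass law should be used for such
  regimes.
* σ is weakly identified under its near-improper prior; its posterior
  should be read as prior-dominated unless the trap layout brackets the
  swarm sites densely.
* Evidence by prior-predictive Monte Carlo has high variance when an
  expert's prior is sharply misaligned with the data; the batch standard
  error should always be inspected.
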