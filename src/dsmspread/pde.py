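"""Diffusion–advection–reaction solver for the expected-abundance field.

The expected number of released male mosquitoes per areal unit,
``lambda(s, t)``, obeys

    d(lambda)/dt = D * [ Laplacian(lambda) - alpha * div(lambda * grad U) ]
                   - mu * lambda,

with zero-flux (reflecting Neumann) boundaries: mosquitoes neither enter
nor leave the modelled domain, they only die.  ``D`` is the isotropic
diffusion coefficient (m^2/day), ``mu`` the mortality rate (1/day),
``alpha`` the strength of chemotaxis toward swarm sites (per reward per
metre) and ``U`` the swarm-attraction utility of :mod:`dsmspread.geometry`.
Note that ``D`` multiplies the bracketed advection term, so the advective
velocity is ``v = D * alpha * grad U``.

Numerics
--------
Finite volumes on the raster of :class:`~dsmspread.geometry.Domain`, with
operator splitting per time step:

1. diffusion — explicit 5-point Laplacian with mirrored ghost cells
   (zero boundary flux, exactly conservative);
2. advection — first-order upwind fluxes on cell faces with face
   velocities from one-sided differences of ``U`` (zero flux through
   boundary faces, exactly conservative);
3. mortality — exact pointwise decay ``exp(-mu * dt)``.

The scheme is positivity-preserving under its step bound and conserves
``total_mass(t) = N0 * exp(-mu * t)`` to machine precision — the primary
solver oracle used by the test suite.  The time step is
``0.9 * min(h^2 / 4D, h / max(|vx| + |vy|))`` capped at 0.05 day.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Domain, SwarmMap, utility_grid

try:  # compiled sub-step kernel; the numpy path below is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

#: hard cap (days) on the internal time step even when stability allows more
MAX_DT_DAYS = 0.05

#: safety factor applied to the stability bound
CFL_SAFETY = 0.9

#: refuse solves that would need more sub-steps than this (pathological
#: parameter draws, e.g. enormous D, are treated as numerically infeasible)
DEFAULT_MAX_STEPS = 200_000


class CFLError(ValueError):
    """A user-supplied time step violates the stability bound."""

    def __init__(self, dt: float, admissible: float):
        self.admissible = admissible
        super().__init__(
            f"time step {dt:g} day violates the stability bound; "
            f"largest admissible step is {admissible:g} day"
        )


@dataclass(frozen=True)
class PDEParams:
    """Process-model parameters.

    Attributes
    ----------
    D : diffusion coefficient, m^2/day (> 0)
    alpha : swarm attractiveness, reward^-1 m^-1 (>= 0)
    mu : mortality rate, 1/day (>= 0)
    sigma : swarm-attraction range, m (> 0)
    """

    D: float
    alpha: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (self.D > 0):
            raise ValueError(f"D must be positive, got {self.D}")
        if self.mu < 0:
            raise ValueError(f"mu must be non-negative, got {self.mu}")
        if not (self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")


@dataclass(frozen=True)
class ReleaseEvent:
    """A point release of marked males at model time zero."""

    location: tuple[float, float]
    n_released: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_released < 0:
            raise ValueError("n_released must be non-negative")


@dataclass
class AbundanceField:
    """Expected marked males per areal unit on the raster, at output times.

    ``values`` has shape ``(n_times, nx, ny)``; ``times`` are days since
    release, sorted ascending.
    """

    values: np.ndarray
    times: np.ndarray
    domain: Domain

    def at_time(self, time: float) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.times, time, atol=1e-9))[0]
        if idx.size == 0:
            raise KeyError(f"time {time} not among solved output times")
        return self.values[idx[0]]

    def value_at(self, point: tuple[float, float], time: float) -> float:
        """Lambda in the cell containing ``point`` at an output time."""
        i, j = self.domain.cell_index(point)
        return float(self.at_time(time)[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: cell indices, centre coordinates, time, lambda."""
        nx, ny = self.domain.shape
        X, Y = self.domain.cell_centers()
        frames = []
        for t, lam in zip(self.times, self.values):
            ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "i": ii.ravel(),
                        "j": jj.ravel(),
                        "easting": X.ravel(),
                        "northing": Y.ravel(),
                        "time": t,
                        "lam": lam.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def total_abundance(field: AbundanceField, time: float) -> float:
    """Expected total number of surviving mosquitoes at an output time."""
    return float(field.at_time(time).sum())


def _face_velocities(
    params: PDEParams, swarms: SwarmMap | None, domain: Domain
) -> tuple[np.ndarray, np.ndarray]:
    """Advective velocity v = D*alpha*grad(U) on cell faces.

    Returns ``(vx, vy)`` with shapes ``(nx+1, ny)`` and ``(nx, ny+1)``;
    boundary faces are zero (no advective flux through the walls).
    """
    nx, ny = domain.shape
    vx = np.zeros((nx + 1, ny))
    vy = np.zeros((nx, ny + 1))
    if params.alpha == 0 or swarms is None:
        return vx, vy
    U = utility_grid(domain, swarms.with_sigma(params.sigma))
    h = domain.cell_size
    coef = params.D * params.alpha
    vx[1:-1, :] = coef * (U[1:, :] - U[:-1, :]) / h
    vy[:, 1:-1] = coef * (U[:, 1:] - U[:, :-1]) / h
    return vx, vy


def _admissible_from_velocities(params: PDEParams, domain: Domain, vx, vy) -> float:
    h = domain.cell_size
    dt = h * h / (4.0 * params.D)
    vmax = float(np.abs(vx).max() + np.abs(vy).max())
    if vmax > 0:
        dt = min(dt, h / vmax)
    return CFL_SAFETY * dt


def admissible_step(params: PDEParams, swarms: SwarmMap | None, domain: Domain) -> float:
    """Largest stable internal time step (days) for these parameters."""
    vx, vy = _face_velocities(params, swarms, domain)
    return _admissible_from_velocities(params, domain, vx, vy)


@_njit(cache=False)
def _substeps_compiled(lam, vxp, vxm, vyp, vym, r, c, decay, n_sub, advect):
    K, NX, NY = lam.shape
    fx = np.empty((NX - 1, NY))
    fy = np.empty((NX, NY - 1))
    for _ in range(n_sub):
        for q in range(K):
            L = lam[q]
            # diffusive fluxes from the pre-step field, then apply
            for i in range(NX - 1):
                for j in range(NY):
                    fx[i, j] = r * (L[i + 1, j] - L[i, j])
            for i in range(NX):
                for j in range(NY - 1):
                    fy[i, j] = r * (L[i, j + 1] - L[i, j])
            for i in range(NX - 1):
                for j in range(NY):
                    L[i, j] += fx[i, j]
                    L[i + 1, j] -= fx[i, j]
            for i in range(NX):
                for j in range(NY - 1):
                    L[i, j] += fy[i, j]
                    L[i, j + 1] -= fy[i, j]
            if advect:
                # upwind advective fluxes from the post-diffusion field
                for i in range(NX - 1):
                    for j in range(NY):
                        fx[i, j] = c * (vxp[i, j] * L[i, j] + vxm[i, j] * L[i + 1, j])
                for i in range(NX):
                    for j in range(NY - 1):
                        fy[i, j] = c * (vyp[i, j] * L[i, j] + vym[i, j] * L[i, j + 1])
                for i in range(NX - 1):
                    for j in range(NY):
                        L[i, j] -= fx[i, j]
                        L[i + 1, j] += fx[i, j]
                for i in range(NX):
                    for j in range(NY - 1):
                        L[i, j] -= fy[i, j]
                        L[i, j + 1] += fy[i, j]
            if decay != 1.0:
                for i in range(NX):
                    for j in range(NY):
                        L[i, j] *= decay
    return lam


def _substeps_numpy(lam, vxp, vxm, vyp, vym, r, c, decay, n_sub, advect):
    for _ in range(n_sub):
        fx = lam[:, 1:, :] - lam[:, :-1, :]
        fx *= r
        fy = lam[:, :, 1:] - lam[:, :, :-1]
        fy *= r
        lam[:, :-1, :] += fx
        lam[:, 1:, :] -= fx
        lam[:, :, :-1] += fy
        lam[:, :, 1:] -= fy
        if advect:
            fx = vxp * lam[:, :-1, :] + vxm * lam[:, 1:, :]
            fx *= c
            fy = vyp * lam[:, :, :-1] + vym * lam[:, :, 1:]
            fy *= c
            lam[:, :-1, :] -= fx
            lam[:, 1:, :] += fx
            lam[:, :, :-1] -= fy
            lam[:, :, 1:] += fy
        if decay != 1.0:
            lam *= decay
    return lam


def _evolve(
    lam: np.ndarray,
    params: PDEParams,
    swarms: SwarmMap | None,
    domain: Domain,
    output_times: np.ndarray,
    dt: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> np.ndarray:
    """Advance a stack of fields ``lam`` (k, nx, ny) from t=0.

    Returns ``(k, n_times, nx, ny)``.  Shared by :func:`solve` and the
    likelihood code, which evolves one unit-mass field per distinct release
    cell and scales by cohort size (the PDE is linear in lambda).
    """
    h = domain.cell_size
    vx, vy = _face_velocities(params, swarms, domain)
    adm = _admissible_from_velocities(params, domain, vx, vy)
    if dt is not None:
        if dt > adm:
            raise CFLError(dt, adm)
        base_dt = dt
    else:
        base_dt = min(adm, MAX_DT_DAYS)

    t_end = float(output_times[-1])
    est_steps = int(np.ceil(t_end / base_dt)) if t_end > 0 else 0
    if est_steps > max_steps:
        raise CFLError(base_dt, adm)

    advect = bool(vx.any() or vy.any())
    vxp, vxm = np.maximum(vx[1:-1, :], 0.0), np.minimum(vx[1:-1, :], 0.0)
    vyp, vym = np.maximum(vy[:, 1:-1], 0.0), np.minimum(vy[:, 1:-1], 0.0)
    substeps = _substeps_compiled if _HAVE_NUMBA else _substeps_numpy

    lam = np.array(lam, dtype=float, copy=True)
    out = np.empty((lam.shape[0], len(output_times)) + lam.shape[1:])
    t = 0.0
    for k_out, t_target in enumerate(np.asarray(output_times, float)):
        span = t_target - t
        if span > 1e-12:
            n_sub = max(int(np.ceil(span / base_dt)), 1)
            sub_dt = span / n_sub
            r = params.D * sub_dt / (h * h)
            decay = float(np.exp(-params.mu * sub_dt))
            c = sub_dt / h
            lam = substeps(lam, vxp, vxm, vyp, vym, r, c, decay, n_sub, advect)
            t = t_target
        out[:, k_out] = lam
    return out


def solve(
    release: ReleaseEvent,
    params: PDEParams,
    swarms: SwarmMap | None,
    domain: Domain,
    output_times,
    dt: float | None = None,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> AbundanceField:
    """Solve the dispersal PDE for one release.

    The whole cohort starts in the single cell containing the release
    point.  ``output_times`` must be sorted and non-negative; a supplied
    ``dt`` is checked against the stability bound and refused (with the
    admissible step reported) if too large.
    """
    times = np.asarray(output_times, float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("output_times must be a non-empty 1-D sequence")
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("output_times must be sorted and non-negative")

    nx, ny = domain.shape
    lam0 = np.zeros((1, nx, ny))
    if release.n_released > 0:
        i, j = domain.cell_index(release.location)
        lam0[0, i, j] = release.n_released
    values = _evolve(lam0, params, swarms, domain, times, dt=dt, max_steps=max_steps)[0]
    return AbundanceField(values=values, times=times, domain=domain)


def solve_unit_releases(
    cells: list[tuple[int, int]],
    params: PDEParams,
    swarms: SwarmMap | None,
    domain: Domain,
    output_times,
    max_steps: int = DEFAULT_MAX_STEPS,
) -> np.ndarray:
    """Evolve a unit mass from each release cell simultaneously.

    Returns ``(n_cells, n_times, nx, ny)``.  Because the PDE is linear,
    the field of any release is ``n_released`` times the unit solution of
    its cell; stacking the solves amortises the per-step cost across
    releases sharing the same parameters.
    """
    times = np.asarray(output_times, float)
    nx, ny = domain.shape
    lam0 = np.zeros((len(cells), nx, ny))
    for k, (i, j) in enumerate(cells):
        lam0[k, i, j] = 1.0
    return _evolve(lam0, params, swarms, domain, times, max_steps=max_steps)
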