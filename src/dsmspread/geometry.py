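"""Spatial domain, local projection, and the swarm-attraction utility field.

Male *Anopheles* mosquitoes aggregate in mating swarms that form at fixed
sites in and around village compounds.  The attraction a mosquito feels
toward those sites is modelled as a squared-exponential kernel summed over
all swarm locations,

    U(s) = sum_l exp(-|s - s_l|^2 / sigma^2),

where ``sigma`` (metres) sets the range beyond which a swarm is effectively
invisible: at distance ``sigma`` the attraction has fallen to exp(-1), about
38% of its value at the site itself.  The advection term of the dispersal
model moves mosquitoes up the gradient of this utility surface.

Everything here works in planar metres.  GPS coordinates are converted with
a local equirectangular projection, which is accurate to well under 0.1% at
the village scale (a couple of kilometres) the model is intended for.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_M = 6_371_000.0

#: side length (m) of one raster cell; one cell is an areal unit of 100 m^2
DEFAULT_CELL_SIZE = 10.0

#: projection validity limit — beyond this the flat-earth approximation breaks
_MAX_PROJECTION_RANGE_M = 100_000.0


@dataclass(frozen=True)
class Domain:
    """A rectangular raster of square cells in planar metre coordinates.

    Cell centres sit at ``origin + (i + 1/2, j + 1/2) * cell_size`` with
    ``i`` indexing easting and ``j`` northing.  A point is assigned to the
    half-open cell ``[left, right) x [bottom, top)`` that contains it.

    Parameters
    ----------
    origin
        South-west corner ``(easting, northing)`` in metres.
    extent
        ``(width, height)`` in metres; both strictly positive.
    cell_size
        Cell side in metres.  The default of 10 m makes each cell one
        areal unit of 100 m^2, the resolution at which abundance is
        expressed and at which trap catchability is defined.
    projected_from_lonlat
        Provenance flag: True when the coordinates were produced by
        :func:`project_lonlat`.
    """

    origin: tuple[float, float]
    extent: tuple[float, float]
    cell_size: float = DEFAULT_CELL_SIZE
    projected_from_lonlat: bool = False

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError(f"extent must be positive, got {self.extent}")

    @property
    def shape(self) -> tuple[int, int]:
        """Grid shape ``(nx, ny)`` — number of cells east and north."""
        nx = int(round(self.extent[0] / self.cell_size))
        ny = int(round(self.extent[1] / self.cell_size))
        return max(nx, 1), max(ny, 1)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Coordinate arrays ``(X, Y)`` of cell centres, shape ``(nx, ny)``."""
        nx, ny = self.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(x, y, indexing="ij")

    def cell_index(self, point: tuple[float, float]) -> tuple[int, int]:
        """Index ``(i, j)`` of the cell containing ``point`` (half-open)."""
        i = int(np.floor((point[0] - self.origin[0]) / self.cell_size))
        j = int(np.floor((point[1] - self.origin[1]) / self.cell_size))
        nx, ny = self.shape
        if not (0 <= i < nx and 0 <= j < ny):
            raise ValueError(f"point {point} lies outside the domain")
        return i, j

    def contains(self, point: tuple[float, float]) -> bool:
        x0, y0 = self.origin
        return (x0 <= point[0] < x0 + self.extent[0]) and (
            y0 <= point[1] < y0 + self.extent[1]
        )


@dataclass(frozen=True)
class SwarmMap:
    """Known swarm-site locations and the shared attraction range sigma (m)."""

    sites: np.ndarray  # (n_sites, 2) planar metres
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sites", np.atleast_2d(np.asarray(self.sites, float)))
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.sites.ndim != 2 or self.sites.shape[1] != 2:
            raise ValueError("sites must be an (n, 2) array of planar coordinates")

    def with_sigma(self, sigma: float) -> "SwarmMap":
        return SwarmMap(self.sites, sigma)


def project_lonlat(
    points: np.ndarray, reference: tuple[float, float]
) -> np.ndarray:
    """Project (lon, lat) degrees to planar metres around ``reference``.

    Local equirectangular projection: eastings scale longitude differences
    by ``cos(latitude)`` at the reference, northings scale latitude
    differences; the reference maps to ``(0, 0)``.  Sub-metre accurate at
    village scale; points more than 100 km from the reference are rejected
    because the flat-earth approximation degrades.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    ref_lon, ref_lat = float(reference[0]), float(reference[1])
    lat0 = np.deg2rad(ref_lat)
    x = np.deg2rad(pts[:, 0] - ref_lon) * EARTH_RADIUS_M * np.cos(lat0)
    y = np.deg2rad(pts[:, 1] - ref_lat) * EARTH_RADIUS_M
    out = np.column_stack([x, y])
    dist = np.hypot(x, y)
    if np.any(dist > _MAX_PROJECTION_RANGE_M):
        raise ValueError(
            "points farther than 100 km from the projection reference; "
            "the local planar projection is invalid at that range"
        )
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def utility(s: np.ndarray, swarms: SwarmMap) -> np.ndarray | float:
    """Attraction U(s) = sum over sites of exp(-|s - s_l|^2 / sigma^2).

    ``s`` may be a single point ``(2,)`` or an array ``(..., 2)``; the
    result matches the leading shape.  Dimensionless and strictly positive.
    """
    pts = np.asarray(s, float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d2 = ((pts[..., None, :] - swarms.sites[None, :, :]) ** 2).sum(axis=-1)
    u = np.exp(-d2 / swarms.sigma**2).sum(axis=-1)
    return float(u[0]) if single else u


def utility_grid(domain: Domain, swarms: SwarmMap) -> np.ndarray:
    """U evaluated at every cell centre; shape ``(nx, ny)``."""
    X, Y = domain.cell_centers()
    pts = np.stack([X, Y], axis=-1).reshape(-1, 2)
    return np.asarray(utility(pts, swarms)).reshape(domain.shape)


def utility_gradient(field: np.ndarray, cell_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Numerical gradient (dU/dx, dU/dy) of a gridded field, in m^-1.

    Central differences in the interior, one-sided at the edges (consistent
    with reflecting boundaries).  Requires at least a 3x3 grid so that the
    interior stencil exists.
    """
    field = np.asarray(field, float)
    if field.shape[0] < 3 or field.shape[1] < 3:
        raise ValueError("gradient needs at least a 3x3 grid")
    gx, gy = np.gradient(field, cell_size, edge_order=1)
    return gx, gy


def utility_gradient_analytic(
    s: np.ndarray, swarms: SwarmMap
) -> np.ndarray:
    """Closed-form gradient of U at points ``s``; used to verify the stencil."""
    pts = np.atleast_2d(np.asarray(s, float))
    diff = pts[:, None, :] - swarms.sites[None, :, :]  # (n, L, 2)
    d2 = (diff**2).sum(axis=-1)
    w = np.exp(-d2 / swarms.sigma**2)
    grad = (-2.0 / swarms.sigma**2) * (diff * w[..., None]).sum(axis=1)
    if np.asarray(s).ndim == 1:
        return grad[0]
    return grad
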