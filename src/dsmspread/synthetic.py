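"""Synthetic villages, MRR campaign designs, and simulated trap catches.

The field data behind the original wild-type analyses are not publicly
deposited, so this module generates datasets with the same statistical
structure: a small village with clustered compounds and swarm sites, four
marking campaigns released at three fixed sites (roughly 500–2100 males
per release, recaptured for 5 days in the first campaign and 7 in the
others), a fifth larger single-site release held out for validation, and
three trap types all within 500 m of the release sites.  Release sizes,
dates-as-indices, and site coordinates follow the published campaign
summary table; the village layout itself is invented (the original swarm
map is not printed) and is reproducible from a seed.

Everything returned is a first-class model object, so each pipeline stage
is testable end-to-end without any download: simulate at a known truth,
fit, predict, and check recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import Domain, SwarmMap, project_lonlat
from .observation import (
    Catchability,
    RECORD_COLUMNS,
    sample_catches,
    sampling_time,
)
from .pde import AbundanceField, PDEParams, ReleaseEvent, solve_unit_releases

#: campaign summary used as the design template: release site GPS
#: (longitude, latitude) and cohort sizes per campaign
SITE_LONLAT = {
    "A": (-4.4724, 11.2347),
    "B": (-4.4755, 11.2342),
    "C": (-4.4718, 11.2318),
}

#: (campaign, site, n_released); campaign 1 had 5 recapture days, others 7
FITTING_RELEASES = [
    (1, "A", 1146), (1, "B", 1589), (1, "C", 1036),
    (2, "A", 878), (2, "B", 655), (2, "C", 734),
    (3, "A", 665), (3, "B", 673), (3, "C", 684),
    (4, "A", 2107), (4, "B", 2013), (4, "C", 1953),
]

#: the held-out fifth campaign: one large single-location release (the
#: published table lists it at the coordinates of site A)
VALIDATION_RELEASE = (5, "A", 5992)

#: plausible trap counts per type (the source table does not print them)
DEFAULT_N_SS, DEFAULT_N_PSC, DEFAULT_N_CFR = 10, 20, 20

#: default generating truth for fixtures — centred on the wild-type
#: posterior regime so synthetic data resemble field conditions
THETA_STAR = {
    "D": 130.0,
    "alpha": 0.07,
    "mu": 0.15,
    "sigma": 30.0,
    "p_ss": 0.29,
    "p_psc": 0.18,
    "p_cfr": 0.03,
}


def default_truth() -> tuple[PDEParams, Catchability]:
    params = PDEParams(
        D=THETA_STAR["D"], alpha=THETA_STAR["alpha"],
        mu=THETA_STAR["mu"], sigma=THETA_STAR["sigma"],
    )
    catch = Catchability(
        p_ss=THETA_STAR["p_ss"], p_psc=THETA_STAR["p_psc"], p_cfr=THETA_STAR["p_cfr"]
    )
    return params, catch


def truth_vector() -> np.ndarray:
    """The default truth in canonical (D, alpha, mu, sigma, p...) order."""
    return np.array([THETA_STAR[k] for k in
                     ("D", "alpha", "mu", "sigma", "p_ss", "p_psc", "p_cfr")])


@dataclass
class MRRDesign:
    """A full campaign design: geometry, releases, traps, swarms."""

    domain: Domain
    swarms: SwarmMap
    compounds: np.ndarray  # (n, 2) planar m
    releases: pd.DataFrame  # release_id, site_id, easting, northing, n_released, n_days
    traps: pd.DataFrame  # trap_id, trap_type, easting, northing
    validation_release_id: str | None = None

    def __post_init__(self) -> None:
        for row in self.releases.itertuples():
            if not self.domain.contains((row.easting, row.northing)):
                raise ValueError(f"release {row.release_id} lies outside the domain")
            if row.n_released <= 0:
                raise ValueError(f"release {row.release_id} has non-positive size")
        for row in self.traps.itertuples():
            if not self.domain.contains((row.easting, row.northing)):
                raise ValueError(f"trap {row.trap_id} lies outside the domain")

    def fitting_releases(self) -> pd.DataFrame:
        if self.validation_release_id is None:
            return self.releases
        return self.releases[self.releases["release_id"] != self.validation_release_id]

    def release_frame(self, fitting_only: bool = True) -> pd.DataFrame:
        """Columns needed by the likelihood: release_id, location, size."""
        rel = self.fitting_releases() if fitting_only else self.releases
        return rel[["release_id", "easting", "northing", "n_released"]].reset_index(
            drop=True
        )

    def recapture_days(self) -> dict[str, int]:
        return dict(zip(self.releases["release_id"], self.releases["n_days"]))


def generate_village(
    n_compounds: int,
    n_swarms: int,
    extent: tuple[float, float],
    seed=None,
    sigma: float = 30.0,
    compound_spread: float | None = None,
    swarm_jitter: float = 12.0,
) -> tuple[SwarmMap, np.ndarray]:
    """Invent a village layout: clustered compounds, swarms jittered nearby.

    Compounds scatter around the village centre with standard deviation
    ``extent/6`` (clipped to stay inside); each swarm site attaches to a
    random compound with a small jitter, reflecting that swarms form in
    and around compounds.  Reproducible from the seed.
    """
    if n_compounds < 1 or n_swarms < 1:
        raise ValueError("need at least one compound and one swarm site")
    rng = np.random.default_rng(seed)
    ext = np.asarray(extent, float)
    centre = ext / 2.0
    spread = compound_spread if compound_spread is not None else ext.min() / 6.0
    compounds = rng.normal(centre, spread, size=(n_compounds, 2))
    compounds = np.clip(compounds, 0.05 * ext, 0.95 * ext)
    hosts = rng.integers(0, n_compounds, size=n_swarms)
    swarm_sites = compounds[hosts] + rng.normal(0.0, swarm_jitter, size=(n_swarms, 2))
    swarm_sites = np.clip(swarm_sites, 0.05 * ext, 0.95 * ext)
    return SwarmMap(swarm_sites, sigma=sigma), compounds


def emulate_epopa_design(
    seed=None,
    cell_size: float = 10.0,
    margin: float = 150.0,
    n_ss: int = DEFAULT_N_SS,
    n_psc: int = DEFAULT_N_PSC,
    n_cfr: int = DEFAULT_N_CFR,
    n_compounds: int = 30,
    sigma: float = THETA_STAR["sigma"],
) -> MRRDesign:
    """A campaign design shaped like the published MRR summary table.

    Twelve fitting releases (4 campaigns x 3 sites, the published cohort
    sizes) plus one held-out validation release of 5992.  The three sites
    are the published GPS locations projected to local planar metres;
    compounds, swarm sites and traps are seeded inventions placed near
    the sites, so every trap sits within 500 m of a release site.
    """
    rng = np.random.default_rng(seed)
    lonlat = np.array(list(SITE_LONLAT.values()))
    ref = tuple(lonlat.mean(axis=0))
    planar = project_lonlat(lonlat, ref)
    lo = planar.min(axis=0) - margin
    hi = planar.max(axis=0) + margin
    width = float(np.ceil((hi[0] - lo[0]) / cell_size) * cell_size)
    height = float(np.ceil((hi[1] - lo[1]) / cell_size) * cell_size)
    domain = Domain(origin=(lo[0], lo[1]), extent=(width, height),
                    cell_size=cell_size, projected_from_lonlat=True)
    sites = {sid: tuple(planar[k]) for k, sid in enumerate(SITE_LONLAT)}

    # compounds cluster around the release sites; swarms attach to compounds
    site_arr = np.array(list(sites.values()))
    host_sites = site_arr[rng.integers(0, len(site_arr), size=n_compounds)]
    compounds = host_sites + rng.normal(0.0, 60.0, size=(n_compounds, 2))
    compounds = np.clip(
        compounds,
        np.asarray(domain.origin) + 0.02 * np.asarray(domain.extent),
        np.asarray(domain.origin) + 0.98 * np.asarray(domain.extent),
    )
    hosts = rng.integers(0, n_compounds, size=n_ss)
    swarm_sites = compounds[hosts] + rng.normal(0.0, 12.0, size=(n_ss, 2))
    swarm_sites = np.clip(
        swarm_sites,
        np.asarray(domain.origin) + 0.02 * np.asarray(domain.extent),
        np.asarray(domain.origin) + 0.98 * np.asarray(domain.extent),
    )
    swarms = SwarmMap(swarm_sites, sigma=sigma)

    rows = []
    for camp, sid, n in FITTING_RELEASES:
        x, y = sites[sid]
        rows.append(
            {
                "release_id": f"mrr{camp}_{sid}",
                "site_id": sid,
                "easting": x,
                "northing": y,
                "n_released": n,
                "n_days": 5 if camp == 1 else 7,
            }
        )
    camp, sid, n = VALIDATION_RELEASE
    rows.append(
        {
            "release_id": f"mrr{camp}_{sid}",
            "site_id": sid,
            "easting": sites[sid][0],
            "northing": sites[sid][1],
            "n_released": n,
            "n_days": 7,
        }
    )
    releases = pd.DataFrame(rows)

    trap_rows = []
    # swarm-sampling traps sit at swarm sites; house traps at compounds
    for k in range(n_ss):
        trap_rows.append(("ss", swarm_sites[k % len(swarm_sites)]))
    psc_hosts = compounds[rng.integers(0, n_compounds, size=n_psc)]
    cfr_hosts = compounds[rng.integers(0, n_compounds, size=n_cfr)]
    for loc in psc_hosts:
        trap_rows.append(("psc", loc))
    for loc in cfr_hosts:
        trap_rows.append(("cfr", loc))
    traps = pd.DataFrame(
        {
            "trap_id": [f"{t}{k:02d}" for k, (t, _) in enumerate(trap_rows)],
            "trap_type": [t for t, _ in trap_rows],
            "easting": [loc[0] for _, loc in trap_rows],
            "northing": [loc[1] for _, loc in trap_rows],
        }
    )
    return MRRDesign(
        domain=domain,
        swarms=swarms,
        compounds=compounds,
        releases=releases,
        traps=traps,
        validation_release_id=f"mrr{camp}_{sid}",
    )


def synthetic_expert_pool() -> tuple[list, list]:
    """A synthetic stand-in for the four elicited expert prior pairs.

    The per-expert hyperparameters of the original elicitation are not
    published, so these are invented Beta survival / log-normal dispersal
    priors chosen to reproduce the qualitative regime the study reports:
    wild-type beliefs centred on high daily survival and dispersal well
    above what the recapture data later supported, and DSM beliefs with
    much higher mortality and very diffuse dispersal.  Returns
    ``(wt_experts, dsm_experts)``, four of each.
    """
    from .priors import ExpertPrior, Prior

    wt_spec = [
        ("E1", (12.0, 2.0), (np.log(100.0), 0.7)),
        ("E2", (8.0, 2.0), (np.log(250.0), 0.9)),
        ("E3", (15.0, 4.0), (np.log(60.0), 0.6)),
        ("E4", (6.0, 1.5), (np.log(150.0), 0.8)),
    ]
    dsm_spec = [
        ("E1", (2.0, 2.0), (np.log(300.0), 1.1)),
        ("E2", (1.5, 3.0), (np.log(800.0), 1.4)),
        ("E3", (3.0, 4.0), (np.log(200.0), 0.9)),
        ("E4", (2.0, 5.0), (np.log(500.0), 1.2)),
    ]
    wt = [
        ExpertPrior(eid, "WT", Prior("beta", surv), Prior("lognormal", disp))
        for eid, surv, disp in wt_spec
    ]
    dsm = [
        ExpertPrior(eid, "DSM", Prior("beta", surv), Prior("lognormal", disp))
        for eid, surv, disp in dsm_spec
    ]
    return wt, dsm


def _release_fields(
    design: MRRDesign,
    params: PDEParams,
    releases: pd.DataFrame,
    max_steps: int = 200_000,
) -> dict[str, AbundanceField]:
    """Solve the PDE for every release (one unit solve per distinct cell)."""
    all_times: dict[str, np.ndarray] = {}
    for row in releases.itertuples():
        n_days = int(row.n_days)
        times = sorted(
            {sampling_time("ss", d) for d in range(0, n_days)}
            | {sampling_time("psc", d) for d in range(1, n_days + 1)}
        )
        all_times[row.release_id] = np.asarray(times)
    union_times = np.unique(np.concatenate(list(all_times.values())))

    cells, cell_idx = [], {}
    for row in releases.itertuples():
        cell = design.domain.cell_index((row.easting, row.northing))
        if cell not in cells:
            cells.append(cell)
        cell_idx[row.release_id] = cells.index(cell)
    unit = solve_unit_releases(
        cells, params, design.swarms, design.domain, union_times, max_steps=max_steps
    )
    fields = {}
    for row in releases.itertuples():
        rid = row.release_id
        keep = np.isin(union_times, all_times[rid])
        fields[rid] = AbundanceField(
            values=unit[cell_idx[rid]][keep] * float(row.n_released),
            times=union_times[keep],
            domain=design.domain,
        )
    return fields


def simulate_mrr(
    design: MRRDesign,
    params: PDEParams,
    catch: Catchability,
    seed=None,
    include_validation: bool = True,
) -> tuple[pd.DataFrame, dict[str, AbundanceField]]:
    """Forward-simulate a trap-catch table from a design and a truth.

    Solves the PDE per release, then draws Poisson(lambda * p) counts per
    trap-day.  Returns both the records and the generating abundance
    fields so recovery tests can compare against the latent truth.
    Per-release RNG streams are spawned from the seed, so regenerating a
    single campaign does not disturb the others.
    """
    releases = design.releases if include_validation else design.fitting_releases()
    fields = _release_fields(design, params, releases)
    master = np.random.default_rng(seed)
    streams = master.spawn(len(releases))
    frames = []
    days = design.recapture_days()
    for stream, row in zip(streams, releases.itertuples()):
        rid = row.release_id
        frames.append(
            sample_catches({rid: fields[rid]}, design.traps, {rid: days[rid]},
                           catch, stream)
        )
    records = pd.concat(frames, ignore_index=True)[RECORD_COLUMNS]
    return records, fields
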