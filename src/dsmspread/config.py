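"""YAML run configuration, prior configuration, and run manifests.

A run config drives the command-line pipeline.  Schema (all lengths in
metres, times in days)::

    seed: 20210916
    domain: {origin: [0, 0], extent: [800, 700], cell_size: 10}
    priors: priors.yaml
    data:
      records: records.csv
      releases: releases.csv
      swarms: swarms.csv          # easting,northing columns + sigma
    mcmc: {chains: 3, iterations: 15000, burn_in: 5000, adapt_every: 200}
    prediction:
      n_released: 5000
      release_location: [x, y]
      horizon: 60
      contour_prob: 0.99
      ensemble_size: 500

The prior config lists the shared priors plus per-expert blocks per
strain::

    shared:
      alpha: {family: lognormal, params: [-2, 1]}
      sigma: {family: lognormal, params: [3.5, 4]}
      catchability:
        ss: {family: beta, params: [10, 20]}
        psc: {family: beta, params: [1.4, 1]}
        cfr: {family: beta, params: [1, 1]}
    experts:
      - {id: E1, strain: WT,
         survival: {family: beta, params: [12, 2]},
         dispersal: {family: lognormal, params: [4.6, 0.7]}}

Every command records a manifest (config hash, seed, package version)
sufficient to reproduce its outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .geometry import Domain, SwarmMap
from .priors import ExpertPrior, Prior, PriorSet


class ConfigError(ValueError):
    """A missing or invalid configuration field, identified by name."""


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"missing required config field {context}{key!r}")
    return mapping[key]


@dataclass
class MCMCSettings:
    chains: int = 3
    iterations: int = 15_000
    burn_in: int = 5_000
    adapt_every: int = 200

    def __post_init__(self) -> None:
        if self.chains <= 0 or self.iterations <= 0:
            raise ConfigError("mcmc.chains and mcmc.iterations must be positive")
        if self.burn_in < 0 or self.adapt_every < 0:
            raise ConfigError("mcmc.burn_in and mcmc.adapt_every must be non-negative")
        if self.burn_in >= self.iterations:
            raise ConfigError("mcmc.burn_in must be smaller than mcmc.iterations")


@dataclass
class PredictionSettings:
    n_released: float = 5000.0
    release_location: tuple[float, float] | None = None
    horizon: float = 60.0
    contour_prob: float = 0.99
    ensemble_size: int = 500

    def __post_init__(self) -> None:
        if self.n_released <= 0:
            raise ConfigError("prediction.n_released must be positive")
        if not (0 < self.contour_prob < 1):
            raise ConfigError("prediction.contour_prob must be in (0, 1)")
        if self.horizon <= 0 or self.ensemble_size <= 0:
            raise ConfigError("prediction.horizon and ensemble_size must be positive")


@dataclass
class RunConfig:
    seed: int
    domain: Domain | None = None
    priors_path: Path | None = None
    records_path: Path | None = None
    releases_path: Path | None = None
    swarms_path: Path | None = None
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    prediction: PredictionSettings = field(default_factory=PredictionSettings)
    raw: dict = field(default_factory=dict)


def load_run_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(_require(raw, "seed", ""))

    domain = None
    if "domain" in raw:
        d = raw["domain"]
        domain = Domain(
            origin=tuple(_require(d, "origin", "domain.")),
            extent=tuple(_require(d, "extent", "domain.")),
            cell_size=float(d.get("cell_size", 10.0)),
        )

    def _path(section: dict, key: str, context: str) -> Path | None:
        if key not in section:
            return None
        p = (path.parent / section[key]).resolve()
        if not p.exists():
            raise ConfigError(f"config field {context}{key!r} refers to a missing file: {p}")
        return p

    data = raw.get("data", {})
    cfg = RunConfig(
        seed=seed,
        domain=domain,
        priors_path=_path(raw, "priors", ""),
        records_path=_path(data, "records", "data."),
        releases_path=_path(data, "releases", "data."),
        swarms_path=_path(data, "swarms", "data."),
        mcmc=MCMCSettings(**raw.get("mcmc", {})),
        prediction=PredictionSettings(
            **{
                k: (tuple(v) if k == "release_location" else v)
                for k, v in raw.get("prediction", {}).items()
            }
        ),
        raw=raw,
    )
    return cfg


# ---------------------------------------------------------------------------
# prior config
# ---------------------------------------------------------------------------

def _dist_from_block(block: dict, context: str) -> Prior:
    return Prior(
        _require(block, "family", context), tuple(_require(block, "params", context))
    )


def load_prior_config(path) -> dict:
    """Parse a prior config; returns shared priors and expert lists.

    Result keys: ``alpha``, ``sigma``, ``catchability`` (dict of Priors),
    ``experts_wt``, ``experts_dsm`` (lists of :class:`ExpertPrior`), and
    optional ``weights`` (per-expert pooling weights).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    shared = raw.get("shared", {})
    out = {
        "alpha": _dist_from_block(shared["alpha"], "shared.alpha.")
        if "alpha" in shared
        else Prior("lognormal", (-2.0, 1.0)),
        "sigma": _dist_from_block(shared["sigma"], "shared.sigma.")
        if "sigma" in shared
        else Prior("lognormal", (3.5, 4.0)),
    }
    catch = shared.get("catchability", {})
    defaults = {"ss": (10.0, 20.0), "psc": (1.4, 1.0), "cfr": (1.0, 1.0)}
    out["catchability"] = {
        t: (
            _dist_from_block(catch[t], f"shared.catchability.{t}.")
            if t in catch
            else Prior("beta", defaults[t])
        )
        for t in ("ss", "psc", "cfr")
    }
    wt, dsm = [], []
    for k, block in enumerate(raw.get("experts", [])):
        ctx = f"experts[{k}]."
        expert = ExpertPrior(
            expert_id=str(_require(block, "id", ctx)),
            strain=_require(block, "strain", ctx),
            survival_dist=_dist_from_block(_require(block, "survival", ctx), ctx + "survival."),
            dispersal_dist=_dist_from_block(
                _require(block, "dispersal", ctx), ctx + "dispersal."
            ),
        )
        (wt if expert.strain == "WT" else dsm).append(expert)
    out["experts_wt"] = wt
    out["experts_dsm"] = dsm
    if "weights" in raw:
        out["weights"] = np.asarray(raw["weights"], float)
    return out


def build_wt_prior_set(prior_cfg: dict) -> PriorSet:
    """Assemble the wild-type inference prior from a parsed prior config."""
    experts = prior_cfg["experts_wt"]
    if not experts:
        raise ConfigError("prior config lists no WT experts")
    return PriorSet.from_experts(
        experts,
        weights=prior_cfg.get("weights"),
        alpha=prior_cfg["alpha"],
        sigma=prior_cfg["sigma"],
        catchability=prior_cfg["catchability"],
    )


def write_prior_config(path, experts: list[ExpertPrior], weights=None,
                       shared: dict | None = None) -> None:
    """Serialise expert blocks (and optional weights) back to YAML."""
    doc: dict = {"experts": []}
    for e in experts:
        doc["experts"].append(
            {
                "id": e.expert_id,
                "strain": e.strain,
                "survival": e.survival_dist.to_dict(),
                "dispersal": e.dispersal_dist.to_dict(),
            }
        )
    if weights is not None:
        doc["weights"] = [float(w) for w in np.asarray(weights, float)]
    if shared is not None:
        doc["shared"] = {
            "alpha": shared["alpha"].to_dict(),
            "sigma": shared["sigma"].to_dict(),
            "catchability": {t: d.to_dict() for t, d in shared["catchability"].items()},
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# swarm / site tables and manifests
# ---------------------------------------------------------------------------

def read_swarms_csv(path, sigma: float | None = None) -> SwarmMap:
    """Swarm sites from a CSV with easting/northing columns.

    ``sigma`` may come from a ``sigma`` column (constant) or the argument.
    """
    import pandas as pd

    df = pd.read_csv(path)
    for col in ("easting", "northing"):
        if col not in df.columns:
            raise ConfigError(f"swarm CSV is missing column {col!r}")
    if sigma is None:
        if "sigma" not in df.columns:
            raise ConfigError("swarm CSV needs a 'sigma' column or an explicit sigma")
        sigma = float(df["sigma"].iloc[0])
    return SwarmMap(df[["easting", "northing"]].to_numpy(), sigma=sigma)


def config_hash(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def write_manifest(out_dir, command: str, config_path, seed: int) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config_sha256": config_hash(config_path),
        "seed": seed,
        "package_version": __version__,
    }
    p = out_dir / "manifest.json"
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return p
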