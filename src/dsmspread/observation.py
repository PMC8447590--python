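"""Hierarchical trap observation model for mark-release-recapture counts.

The latent number of marked males in a trap's cell at sampling time is
Poisson with mean ``lambda`` (from the dispersal PDE); the trap then
captures each of them independently with a trap-type-specific catchability
``p``.  Marginally a Binomial(n, p) thinning of a Poisson(lambda) count is
Poisson(lambda * p), so the infinite sum over latent outcomes collapses
analytically — the likelihood below uses that identity (the brute-force
truncated sum is kept in the test suite as an independent oracle).

Trap types
----------
``ss``   swarm sampling with nets in the evening,
``psc``  pyrethroid spray catches inside houses in the morning,
``cfr``  humidified clay pots in rooms, checked in the morning.

Within-day sampling times are fixed at the midpoints of the windows the
field protocol reports: releases at 16:00 define t = 0; swarm sampling at
20:00 the same evening (t = 4 h) and nightly thereafter; spray and
clay-pot collections at 06:30 each following morning (t = 14.5 h, then
every 24 h).  A recapture day ``k`` therefore maps to model time
``k + 4/24`` days for ``ss`` (evenings k = 0, 1, ...) and
``(k - 1) + 14.5/24`` days for ``psc``/``cfr`` (mornings k = 1, 2, ...).

Captured mosquitoes are not removed from the expected field: recaptures
are a small fraction of each release and the process model carries no
depletion term.  False positives and negatives are taken as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .pde import AbundanceField

TRAP_TYPES = ("ss", "psc", "cfr")

#: model-time offsets (days) of the first sampling of each trap type
_SS_OFFSET = 4.0 / 24.0
_MORNING_OFFSET = 14.5 / 24.0

RECORD_COLUMNS = [
    "release_id",
    "trap_id",
    "trap_type",
    "easting",
    "northing",
    "day",
    "count",
]


@dataclass(frozen=True)
class TrapRecord:
    """One observed count: a trap, a recapture day, a release."""

    release_id: str
    trap_id: str
    trap_type: str
    location: tuple[float, float]
    day: int
    count: int

    def __post_init__(self) -> None:
        if self.trap_type not in TRAP_TYPES:
            raise ValueError(f"unknown trap type {self.trap_type!r}")
        if self.day < 0:
            raise ValueError("recapture day must be non-negative")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError("count must be a non-negative integer")


@dataclass(frozen=True)
class Catchability:
    """Trap-type capture probabilities, each in (0, 1)."""

    p_ss: float
    p_psc: float
    p_cfr: float

    def __post_init__(self) -> None:
        for name in ("p_ss", "p_psc", "p_cfr"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def get(self, trap_type: str) -> float:
        return {"ss": self.p_ss, "psc": self.p_psc, "cfr": self.p_cfr}[trap_type]

    def as_array(self) -> np.ndarray:
        return np.array([self.p_ss, self.p_psc, self.p_cfr])


def sampling_time(trap_type: str, day: int) -> float:
    """Model time (days since release) of a trap type's sampling on a day."""
    if trap_type == "ss":
        return day + _SS_OFFSET
    if trap_type in ("psc", "cfr"):
        if day < 1:
            raise ValueError("morning collections start on recapture day 1")
        return (day - 1) + _MORNING_OFFSET
    raise ValueError(f"unknown trap type {trap_type!r}")


def poisson_logpmf(y, mean) -> np.ndarray:
    """log P(Y = y) for Y ~ Poisson(mean), safe at mean = 0."""
    y = np.asarray(y, float)
    mean = np.asarray(mean, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = y * np.log(mean) - mean - special.gammaln(y + 1.0)
    lp = np.where(mean > 0, lp, np.where(y == 0, 0.0, -np.inf))
    return lp


def trap_log_likelihood(y: int, lambda_local: float, p: float) -> float:
    """Marginal log P(y | lambda, p): Poisson thinning gives Poisson(lambda*p)."""
    if lambda_local < 0:
        raise ValueError("expected abundance must be non-negative")
    if not (0.0 <= p <= 1.0):
        raise ValueError("catchability must lie in [0, 1]")
    if y < 0 or int(y) != y:
        raise ValueError("count must be a non-negative integer")
    return float(poisson_logpmf(y, lambda_local * p))


def records_to_frame(records: list[TrapRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "release_id": r.release_id,
                "trap_id": r.trap_id,
                "trap_type": r.trap_type,
                "easting": r.location[0],
                "northing": r.location[1],
                "day": r.day,
                "count": r.count,
            }
            for r in records
        ],
        columns=RECORD_COLUMNS,
    )


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Schema-check a record table; returns it with canonical dtypes."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table is missing columns: {missing}")
    rec = records[RECORD_COLUMNS].copy()
    for row, t in zip(rec.index, rec["trap_type"]):
        if t not in TRAP_TYPES:
            raise ValueError(f"row {row}: unknown trap type {t!r}")
    if (rec["count"] < 0).any():
        bad = rec.index[rec["count"] < 0][0]
        raise ValueError(f"row {bad}: negative count")
    if (rec["day"] < 0).any():
        bad = rec.index[rec["day"] < 0][0]
        raise ValueError(f"row {bad}: negative recapture day")
    rec["count"] = rec["count"].astype(int)
    rec["day"] = rec["day"].astype(int)
    return rec


def record_times(records: pd.DataFrame) -> pd.Series:
    """Model sampling time of every record (days since its release)."""
    return pd.Series(
        [sampling_time(t, d) for t, d in zip(records["trap_type"], records["day"])],
        index=records.index,
        name="time",
    )


def required_output_times(records: pd.DataFrame) -> dict[str, np.ndarray]:
    """Sorted unique solver output times needed per release id."""
    rec = validate_records(records)
    times = record_times(rec)
    return {
        rid: np.unique(times[rec["release_id"] == rid].to_numpy())
        for rid in rec["release_id"].unique()
    }


def joint_log_likelihood(
    records: pd.DataFrame,
    fields: dict[str, AbundanceField],
    catch: Catchability,
) -> float:
    """Sum of marginal trap log-likelihoods over all records.

    ``fields`` maps each release id to its solved abundance field, which
    must contain every record's sampling time among its output times.
    Records outside the spatial or temporal coverage are rejected with the
    offending row identified.
    """
    rec = validate_records(records)
    if len(rec) == 0:
        return 0.0
    total = 0.0
    times = record_times(rec)
    for row in rec.itertuples():
        rid = row.release_id
        if rid not in fields:
            raise ValueError(f"row {row.Index}: no solved field for release {rid!r}")
        field = fields[rid]
        point = (row.easting, row.northing)
        try:
            lam = field.value_at(point, times[row.Index])
        except (KeyError, ValueError) as err:
            raise ValueError(
                f"row {row.Index} (release {rid!r}, trap {row.trap_id!r}): {err}"
            ) from err
        total += trap_log_likelihood(row.count, lam, catch.get(row.trap_type))
    return float(total)


def sample_catches(
    fields: dict[str, AbundanceField],
    traps: pd.DataFrame,
    recapture_days: dict[str, int] | int,
    catch: Catchability,
    rng,
) -> pd.DataFrame:
    """Draw a synthetic trap-catch table from solved abundance fields.

    ``traps`` needs columns ``trap_id, trap_type, easting, northing``.
    ``recapture_days`` gives the number of recapture days per release
    (an int applies to all): swarm sampling runs evenings 0..n-1, morning
    collections days 1..n.  Counts are Poisson(lambda * p) per trap-day,
    reproducible for a given generator.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    rows = []
    for rid, field in fields.items():
        n_days = recapture_days[rid] if isinstance(recapture_days, dict) else recapture_days
        for trap in traps.itertuples():
            days = range(0, n_days) if trap.trap_type == "ss" else range(1, n_days + 1)
            for day in days:
                t = sampling_time(trap.trap_type, day)
                lam = field.value_at((trap.easting, trap.northing), t)
                mean = lam * catch.get(trap.trap_type)
                rows.append(
                    {
                        "release_id": rid,
                        "trap_id": trap.trap_id,
                        "trap_type": trap.trap_type,
                        "easting": trap.easting,
                        "northing": trap.northing,
                        "day": day,
                        "count": int(rng.poisson(mean)),
                    }
                )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records_csv(records: pd.DataFrame, path) -> None:
    validate_records(records).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    try:
        rec = pd.read_csv(path)
    except Exception as err:  # pragma: no cover - passthrough context
        raise ValueError(f"cannot parse record CSV {path}: {err}") from err
    return validate_records(rec)
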