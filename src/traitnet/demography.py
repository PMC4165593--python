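"""Demographic rates and derived traits from permanent-plot census data.

Species performance after disturbance is summarized by three annualized
rates computed from yearly censuses of trees with DBH >= 10 cm:

* the population change rate ``lambda`` over a multi-year period,
* the recruitment rate (per-capita ingrowth past the 10 cm DBH threshold),
* the mortality rate, excluding trees directly wounded or poisoned by
  silvicultural treatments so that only the intrinsic response remains.

The module also derives three species-level attributes used alongside leaf
and wood traits: maximum diameter ``Dm`` (95th percentile of the
left-truncated DBH distribution), ellipsoidal seed volume ``SV``, and growth
potential ``RDIR`` (95th percentile of relative diameter increment rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DBH_THRESHOLD_CM = 10.0
#: fraction of the species' absolute maximum DBH below which diameters are
#: discarded before taking the 95th percentile
LEFT_TRUNCATION_FRACTION = 0.1
UPPER_QUANTILE = 0.95

CENSUS_COLUMNS = ["tree_id", "species_id", "year", "dbh", "status", "excluded"]
CENSUS_STATUSES = frozenset({"alive", "recruited", "dead"})


@dataclass(frozen=True)
class DemographicRates:
    """Annualized demographic summary for one species over one period."""

    species_id: str
    N0: int
    NT: int
    T: float
    lam: float
    rec_rate: float
    mort_rate: float


# ---------------------------------------------------------------------------
# Population change rate
# ---------------------------------------------------------------------------

def pop_change_rate(
    N0: float, NT: float, T: float, convention: str = "geometric"
) -> float:
    """Annualized population change rate from start/end population sizes.

    Parameters
    ----------
    N0, NT
        Number of living trees at the start and end of the period.
    T
        Period length in years.
    convention
        ``"geometric"`` returns ``(NT/N0)**(1/T) - 1``; ``"log"`` returns
        ``ln(NT/N0)/T``. Both vanish when the population is unchanged.
    """
    if N0 <= 0:
        raise ValueError(f"N0 must be positive, got {N0}")
    if T <= 0:
        raise ValueError(f"T must be positive, got {T}")
    if NT < 0:
        raise ValueError(f"NT must be nonnegative, got {NT}")
    if convention == "geometric":
        return (NT / N0) ** (1.0 / T) - 1.0
    if convention == "log":
        if NT == 0:
            raise ValueError("log convention undefined for NT = 0")
        return math.log(NT / N0) / T
    raise ValueError(f"unknown convention {convention!r}")


# ---------------------------------------------------------------------------
# Annualized event rates (recruitment / mortality)
# ---------------------------------------------------------------------------

def annual_event_rate(
    yearly_events: Sequence[float],
    yearly_alive: Sequence[float],
    pooling: str = "mean_ratio",
) -> float:
    """Annualized per-capita event rate from yearly event and alive counts.

    ``yearly_events[t]`` is the number of events (recruitments or deaths) in
    the interval starting at census ``t``; ``yearly_alive[t]`` the number of
    living trees at the start of that interval. The default takes advantage
    of the yearly surveys by averaging the annual ratios,
    ``(1/T) * sum(n_t / N_t)``; ``pooling="pooled"`` instead returns
    ``sum(n_t) / sum(N_t)``.
    """
    n = np.asarray(yearly_events, dtype=float)
    N = np.asarray(yearly_alive, dtype=float)
    if n.shape != N.shape or n.ndim != 1 or n.size == 0:
        raise ValueError("event and alive counts must be equal-length 1-d sequences")
    if np.any(N <= 0):
        raise ValueError("all yearly alive counts must be positive")
    if np.any(n < 0):
        raise ValueError("event counts must be nonnegative")
    if pooling == "mean_ratio":
        return float(np.mean(n / N))
    if pooling == "pooled":
        return float(n.sum() / N.sum())
    raise ValueError(f"unknown pooling {pooling!r}")


# ---------------------------------------------------------------------------
# Census handling
# ---------------------------------------------------------------------------

def read_census(path) -> pd.DataFrame:
    """Read a long-format census CSV (tree_id, species_id, year, dbh, status,
    excluded) and validate the column set."""
    census = pd.read_csv(path, dtype={"tree_id": str, "species_id": str})
    missing = set(CENSUS_COLUMNS) - set(census.columns)
    if missing:
        raise ValueError(f"census file missing columns: {sorted(missing)}")
    census["excluded"] = census["excluded"].astype(bool)
    return census


def validate_census(census: pd.DataFrame) -> None:
    """Raise if the census table violates its structural invariants."""
    bad_status = set(census["status"]) - CENSUS_STATUSES
    if bad_status:
        raise ValueError(f"unknown status values: {sorted(bad_status)}")
    living = census[census["status"].isin(["alive", "recruited"])]
    if (living["dbh"] < DBH_THRESHOLD_CM).any():
        raise ValueError("alive/recruited record below the 10 cm DBH threshold")
    per_tree = census.sort_values("year").groupby("tree_id", sort=False)
    n_recruit = per_tree["status"].apply(lambda s: (s == "recruited").sum())
    if (n_recruit > 1).any():
        raise ValueError("a tree is recruited more than once")
    for tree, grp in per_tree:
        dead = grp.loc[grp["status"] == "dead", "year"]
        if len(dead) and (grp["year"] > dead.iloc[0]).any():
            raise ValueError(f"tree {tree} has records after its death year")


def rates_from_census(
    census: pd.DataFrame,
    species_id: str,
    period: tuple[int, int],
    lambda_convention: str = "geometric",
    rate_pooling: str = "mean_ratio",
) -> DemographicRates:
    """Assemble the three demographic rates for one species from a census.

    Living counts ``N_t`` include every non-dead record in year ``t``;
    recruits are trees whose first record at or above the 10 cm threshold
    falls in an interior year of the period; deaths of trees flagged
    ``excluded`` (wounded or poisoned during silvicultural operations) are
    not counted as mortality events.
    """
    year_start, year_end = period
    sp = census[census["species_id"] == species_id]
    if sp.empty:
        raise ValueError(f"species {species_id!r} not present in census")
    sp = sp[(sp["year"] >= year_start) & (sp["year"] <= year_end)]

    alive_mask = sp["status"].isin(["alive", "recruited"]) & (
        sp["dbh"] >= DBH_THRESHOLD_CM
    )
    alive = sp[alive_mask]
    N_by_year = alive.groupby("year")["tree_id"].nunique()
    years = list(range(year_start, year_end + 1))
    N = np.array([int(N_by_year.get(y, 0)) for y in years])
    if N[0] == 0:
        raise ValueError(
            f"species {species_id!r} absent at period start {year_start}: "
            "rates not analyzable"
        )

    # recruit year = first year a tree is recorded at/above the threshold;
    # trees already present in the first census year are the initial cohort
    first_seen = alive.groupby("tree_id")["year"].min()
    recruit_years = first_seen[first_seen > year_start]
    deaths = sp[(sp["status"] == "dead") & (~sp["excluded"])]

    n_rec = np.zeros(len(years) - 1)
    n_mort = np.zeros(len(years) - 1)
    for i, y in enumerate(years[:-1]):
        # events in the interval (y, y+1] are attributed to denominator N_y
        n_rec[i] = int((recruit_years == y + 1).sum())
        n_mort[i] = deaths[deaths["year"] == y + 1]["tree_id"].nunique()

    interval_N = N[:-1]
    if np.any(interval_N == 0):
        raise ValueError(
            f"species {species_id!r} has a year with no living trees inside "
            "the period"
        )
    T = float(year_end - year_start)
    return DemographicRates(
        species_id=species_id,
        N0=int(N[0]),
        NT=int(N[-1]),
        T=T,
        lam=pop_change_rate(N[0], N[-1], T, convention=lambda_convention),
        rec_rate=annual_event_rate(n_rec, interval_N, pooling=rate_pooling),
        mort_rate=annual_event_rate(n_mort, interval_N, pooling=rate_pooling),
    )


def species_table_from_census(
    census: pd.DataFrame,
    period: tuple[int, int],
    **kwargs,
) -> pd.DataFrame:
    """Demographic rates for every species analyzable over the period."""
    rows = []
    for sp in sorted(census["species_id"].unique()):
        try:
            r = rates_from_census(census, sp, period, **kwargs)
        except ValueError:
            continue
        rows.append(
            {
                "species_id": r.species_id,
                "N0": r.N0,
                "NT": r.NT,
                "lambda": r.lam,
                "rec": r.rec_rate,
                "mort": r.mort_rate,
            }
        )
    return pd.DataFrame(rows).set_index("species_id")


# ---------------------------------------------------------------------------
# Derived traits
# ---------------------------------------------------------------------------

def max_diameter(dbh_sample: Sequence[float], quantile: float = UPPER_QUANTILE) -> float:
    """Species maximum diameter Dm: the 95th percentile of the left-truncated
    DBH distribution (diameters above 10% of the species absolute maximum).

    Linear interpolation between order statistics is used for the quantile.
    """
    d = np.asarray(dbh_sample, dtype=float)
    if d.size == 0:
        raise ValueError("empty DBH sample")
    if np.any(d <= 0):
        raise ValueError("DBH values must be positive")
    kept = d[d >= LEFT_TRUNCATION_FRACTION * d.max()]
    return float(np.quantile(kept, quantile))


def seed_volume(L: float, W: float, D: float) -> float:
    """Ellipsoidal seed volume (pi/6 * L * W * D) from the seed's length,
    width and depth taken as the ellipsoid diameters."""
    if L <= 0 or W <= 0 or D <= 0:
        raise ValueError("seed dimensions must be positive")
    return math.pi / 6.0 * L * W * D


def growth_potential(
    dbh_series: pd.DataFrame,
    window: tuple[int, int] = (2000, 2003),
    quantile: float = UPPER_QUANTILE,
    per_tree: bool = False,
) -> float:
    """Growth potential RDIR: the 95th percentile of relative diameter
    increment rates, ``(D_{t+1} - D_t) / (D_t * dt)``, pooled over all tree
    intervals inside the window.

    Parameters
    ----------
    dbh_series
        Long table with columns ``tree_id``, ``year``, ``dbh``.
    window
        Inclusive calendar-year window; only intervals with both endpoints
        inside it contribute.
    per_tree
        If true, average increments within each tree before taking the
        quantile across trees.
    """
    df = dbh_series[
        (dbh_series["year"] >= window[0]) & (dbh_series["year"] <= window[1])
    ].sort_values(["tree_id", "year"])
    increments: list[float] = []
    tree_means: list[float] = []
    for _, grp in df.groupby("tree_id", sort=False):
        years = grp["year"].to_numpy(dtype=float)
        dbh = grp["dbh"].to_numpy(dtype=float)
        if len(years) < 2:
            continue
        dt = np.diff(years)
        rate = np.diff(dbh) / (dbh[:-1] * dt)
        increments.extend(rate.tolist())
        tree_means.append(float(rate.mean()))
    if not increments:
        raise ValueError("no tree has two DBH observations inside the window")
    pooled = tree_means if per_tree else increments
    return float(np.quantile(pooled, quantile))
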