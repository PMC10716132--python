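"""Stochastic ZEV trip assignment and link-hour volume accumulation.

ZEV trips are flagged per origin tract by an exact-count rule: for a tract
with ownership fraction p and n light-duty trips, exactly round(p n) trips
are sampled uniformly without replacement.  Medium- and heavy-duty trips are
flagged at county-level fractions (no tract-level truck ownership exists).
Flagged trips then accumulate onto the network as expanded link-hour volumes
and per-tract electric vehicle miles traveled (eVMT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Mapping

import numpy as np
import pandas as pd

METERS_PER_MILE = 1609.344
PCE_TRUCK = 3.5  # one truck impedes flow like 3.5 passenger cars


@dataclass
class LinkHourVolume:
    """Expanded vehicle counts by (link, hour, vclass, technology)."""

    counts: pd.DataFrame  # columns: link_id, hour, vclass, tech, count
    pce_volume: pd.DataFrame  # columns: link_id, hour, pce


@dataclass
class EVMTResult:
    """Electric vehicle miles traveled attributed to tracts."""

    miles: pd.Series  # index tract_id
    total: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_zev_trips(trips: pd.DataFrame,
                     ldv_ownership_fraction: Mapping[str, float] | pd.Series,
                     mdv_fraction: float, hdv_fraction: float,
                     seed: int) -> pd.DataFrame:
    """Flag ZEV trips by the exact-count rule; deterministic under seed."""
    frac = pd.Series(ldv_ownership_fraction, dtype=float)
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("tract ownership fractions must lie in [0, 1]")
    for name, p in (("mdv_fraction", mdv_fraction),
                    ("hdv_fraction", hdv_fraction)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")

    rng = np.random.default_rng(seed)
    is_zev = np.zeros(len(trips), dtype=bool)
    positions = np.arange(len(trips))

    ldv = trips["vclass"].to_numpy() == "LDV"
    origin = trips["origin_tract"].to_numpy()
    for tract in sorted(pd.unique(origin[ldv])):
        pool = positions[ldv & (origin == tract)]
        p = float(frac.get(tract, 0.0))
        k = _round_half_up(p * len(pool))
        if k > 0:
            is_zev[rng.choice(pool, size=k, replace=False)] = True

    for vclass, p in (("MDV", mdv_fraction), ("HDV", hdv_fraction)):
        pool = positions[trips["vclass"].to_numpy() == vclass]
        k = _round_half_up(p * len(pool))
        if k > 0:
            is_zev[rng.choice(pool, size=k, replace=False)] = True

    out = trips.copy()
    out["is_zev"] = is_zev
    return out


def _exploded(trips: pd.DataFrame) -> pd.DataFrame:
    """One row per (trip, route link), preserving trip attributes."""
    out = trips[["trip_id", "vclass", "depart_hour", "is_zev", "route"]].copy()
    out = out.explode("route", ignore_index=True)
    return out.rename(columns={"route": "link_id"})


def accumulate_link_volumes(trips: pd.DataFrame, links: pd.DataFrame,
                            expansion_factor: float = 1.0,
                            pce_truck: float = PCE_TRUCK) -> LinkHourVolume:
    """Expand trips onto their route links at the departure hour.

    Each trip contributes ``expansion_factor`` vehicles to every link of its
    route in its single departure hour.  The passenger-car-equivalent volume
    counts a medium/heavy truck as ``pce_truck`` cars.
    """
    if expansion_factor <= 0:
        raise ValueError("expansion_factor must be positive")
    if len(trips) == 0:
        empty = pd.DataFrame(columns=["link_id", "hour", "vclass", "tech",
                                      "count"])
        return LinkHourVolume(counts=empty,
                              pce_volume=pd.DataFrame(
                                  columns=["link_id", "hour", "pce"]))
    ex = _exploded(trips)
    unknown = ~ex["link_id"].isin(set(links["link_id"]))
    if unknown.any():
        bad = ex.loc[unknown, "trip_id"].iloc[0]
        raise ValueError(f"trip {bad} routes over an unknown link")
    ex["tech"] = np.where(ex["is_zev"], "ZEV", "ICEV_like")
    counts = (ex.groupby(["link_id", "depart_hour", "vclass", "tech"],
                         observed=True)
              .size().mul(expansion_factor).rename("count").reset_index()
              .rename(columns={"depart_hour": "hour"}))
    ex["pce"] = np.where(ex["vclass"] == "LDV", 1.0, pce_truck)
    pce = (ex.groupby(["link_id", "depart_hour"], observed=True)["pce"]
           .sum().mul(expansion_factor).rename("pce").reset_index()
           .rename(columns={"depart_hour": "hour"}))
    return LinkHourVolume(counts=counts, pce_volume=pce)


def compute_evmt(trips: pd.DataFrame, links: pd.DataFrame,
                 tracts: pd.DataFrame,
                 expansion_factor: float = 1.0) -> EVMTResult:
    """Per-tract eVMT: miles driven by ZEV-flagged trips.

    Each route link contributes its length (in miles, expanded) to the tract
    containing the link midpoint.
    """
    link_info = links.set_index("link_id")
    if link_info["tract_id"].isna().any():
        raise ValueError("link midpoint outside all tracts")
    zev = trips[trips["is_zev"]]
    miles = pd.Series(0.0, index=tracts["tract_id"])
    if len(zev):
        ex = _exploded(zev)
        ex["miles"] = (link_info["length_m"].reindex(ex["link_id"]).to_numpy()
                       / METERS_PER_MILE * expansion_factor)
        ex["tract_id"] = link_info["tract_id"].reindex(ex["link_id"]).to_numpy()
        got = ex.groupby("tract_id")["miles"].sum()
        miles = miles.add(got, fill_value=0.0)
    return EVMTResult(miles=miles, total=float(miles.sum()))


def compute_vmt(trips: pd.DataFrame, links: pd.DataFrame,
                tracts: pd.DataFrame,
                expansion_factor: float = 1.0) -> EVMTResult:
    """Total VMT by all trips, same midpoint attribution as eVMT."""
    all_flagged = trips.copy()
    all_flagged["is_zev"] = True
    return compute_evmt(all_flagged, links, tracts, expansion_factor)


def repeat_assignment(trips: pd.DataFrame,
                      ldv_ownership_fraction: Mapping[str, float] | pd.Series,
                      mdv_fraction: float, hdv_fraction: float,
                      k: int, base_seed: int) -> List[np.ndarray]:
    """k independent ZEV selections with consecutive seeds."""
    if k < 2:
        raise ValueError("need at least 2 replicates")
    return [
        select_zev_trips(trips, ldv_ownership_fraction, mdv_fraction,
                         hdv_fraction, seed=base_seed + i)["is_zev"].to_numpy()
        for i in range(k)
    ]
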