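"""Process-resolved link emission inventory.

Fine vehicle-category emission rates are first collapsed onto the network's
weight classes by fleet-share weighting,

    ER_class(j, i, process) = sum_k ER_cat(k, i, process) * VP(k),

where VP(k) is the fleet share of category k within weight class j.  The
class rates are then combined with expanded link-hour volumes and trip
start/stop activity to produce gram emissions per link, hour, pollutant and
process: running exhaust and brake/tire wear scale with miles traveled,
start exhaust is charged on each trip's first route link at its departure
hour, and idling on the last link.  In a with-ZEV scenario, ZEV-flagged
vehicles contribute zero running, start and idling emissions but full
brake/tire wear; a without-ZEV scenario treats the entire fleet as
combustion vehicles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from zevequity.assignment import METERS_PER_MILE, LinkHourVolume
from zevequity.region import PROCESSES, TAILPIPE_PROCESSES

GRAMS_PER_TON = 1e6
DAYS_PER_YEAR = 365

_EXPECTED_UNITS = {"running_exhaust": "g/mile", "start_exhaust": "g/start",
                   "idling": "g/hour", "brake_tire_wear": "g/mile"}


@dataclass
class LinkEmissions:
    """Gram emissions by (link, hour, pollutant, process) for one scenario."""

    grams: pd.DataFrame  # columns: link_id, hour, pollutant, process, grams
    scenario: str


def aggregate_rates(rates: pd.DataFrame,
                    weight_map: pd.DataFrame) -> pd.DataFrame:
    """Fleet-share-weighted emission rates per weight class.

    Returns a frame with columns (weight_class, pollutant, tech, process,
    rate).  Every weight class must have at least one member category, and
    the aggregated rate is a convex combination of member rates.
    """
    if "units" in rates:
        bad = rates[rates["units"] != rates["process"].map(_EXPECTED_UNITS)]
        if len(bad):
            raise ValueError(
                f"unit mismatch in rate table: {bad.iloc[0].to_dict()}")
    share_sums = weight_map.groupby("weight_class")["vp_share"].sum()
    if not np.allclose(share_sums, 1.0, atol=1e-9):
        raise ValueError("vehicle-population shares must sum to 1 per class")
    merged = rates.merge(weight_map, on="category", how="inner")
    empty = set(weight_map["weight_class"]) - set(merged["weight_class"])
    if empty:
        raise ValueError(f"weight classes with no member rates: {empty}")
    merged["weighted"] = merged["rate"] * merged["vp_share"]
    out = (merged.groupby(["weight_class", "pollutant", "tech", "process"],
                          observed=True)["weighted"]
           .sum().rename("rate").reset_index())
    return out


def _rate_lookup(class_rates: pd.DataFrame) -> pd.Series:
    return class_rates.set_index(
        ["weight_class", "pollutant", "tech", "process"])["rate"]


def compute_link_emissions(volumes: LinkHourVolume, trips: pd.DataFrame,
                           class_rates: pd.DataFrame, links: pd.DataFrame,
                           scenario: str, idle_minutes: float = 1.0,
                           expansion_factor: float = 1.0) -> LinkEmissions:
    """Gram emissions per link-hour, pollutant and process.

    ``scenario`` is "with_zev" (ZEV-flagged vehicles use ZEV rates) or
    "without_zev" (every vehicle treated as combustion, the all-ICEV
    baseline).
    """
    if scenario not in ("with_zev", "without_zev"):
        raise ValueError(f"unknown scenario {scenario!r}")
    lookup = _rate_lookup(class_rates)
    length_mi = links.set_index("link_id")["length_m"] / METERS_PER_MILE
    pollutants = sorted(class_rates["pollutant"].unique())

    def effective_tech(tech: np.ndarray) -> np.ndarray:
        if scenario == "without_zev":
            return np.full(len(tech), "ICEV")
        return np.where(tech == "ZEV", "ZEV", "ICEV")

    pieces = []

    # Distance-based processes from link-hour volumes.
    vol = volumes.counts.copy()
    if len(vol):
        vol["etech"] = effective_tech(vol["tech"].to_numpy())
        vol["miles"] = (length_mi.reindex(vol["link_id"]).to_numpy()
                        * vol["count"].to_numpy())
        for process in ("running_exhaust", "brake_tire_wear"):
            for pollutant in pollutants:
                key = pd.MultiIndex.from_arrays(
                    [vol["vclass"], np.full(len(vol), pollutant),
                     vol["etech"], np.full(len(vol), process)])
                rate = lookup.reindex(key).to_numpy()
                if np.isnan(rate).any():
                    raise ValueError(
                        f"missing rate for {process}/{pollutant}")
                grams = vol["miles"].to_numpy() * rate
                pieces.append(pd.DataFrame({
                    "link_id": vol["link_id"], "hour": vol["hour"],
                    "pollutant": pollutant, "process": process,
                    "grams": grams}))

    # Event-based processes from the trip table.
    if len(trips):
        ev = pd.DataFrame({
            "vclass": trips["vclass"],
            "hour": trips["depart_hour"],
            "first_link": [r[0] for r in trips["route"]],
            "last_link": [r[-1] for r in trips["route"]],
            "etech": effective_tech(
                np.where(trips["is_zev"].to_numpy(), "ZEV", "ICEV_like")),
        })
        for process, link_col, scale in (
                ("start_exhaust", "first_link", 1.0),
                ("idling", "last_link", idle_minutes / 60.0)):
            grp = (ev.groupby([link_col, "hour", "vclass", "etech"],
                              observed=True)
                   .size().mul(expansion_factor * scale)
                   .rename("n").reset_index()
                   .rename(columns={link_col: "link_id"}))
            for pollutant in pollutants:
                key = pd.MultiIndex.from_arrays(
                    [grp["vclass"], np.full(len(grp), pollutant),
                     grp["etech"], np.full(len(grp), process)])
                rate = lookup.reindex(key).to_numpy()
                if np.isnan(rate).any():
                    raise ValueError(
                        f"missing rate for {process}/{pollutant}")
                pieces.append(pd.DataFrame({
                    "link_id": grp["link_id"], "hour": grp["hour"],
                    "pollutant": pollutant, "process": process,
                    "grams": grp["n"].to_numpy() * rate}))

    if not pieces:
        grams = pd.DataFrame(columns=["link_id", "hour", "pollutant",
                                      "process", "grams"])
        return LinkEmissions(grams=grams, scenario=scenario)
    grams = (pd.concat(pieces, ignore_index=True)
             .groupby(["link_id", "hour", "pollutant", "process"],
                      observed=True)["grams"]
             .sum().reset_index())
    return LinkEmissions(grams=grams, scenario=scenario)


def scenario_difference(without: LinkEmissions,
                        with_: LinkEmissions) -> pd.DataFrame:
    """Elementwise reduction (without − with); nonnegative by construction."""
    keys = ["link_id", "hour", "pollutant", "process"]
    merged = without.grams.merge(with_.grams, on=keys, how="outer",
                                 suffixes=("_wo", "_w"), indicator=True)
    tailpipe = merged["process"].isin(TAILPIPE_PROCESSES)
    # With-ZEV tables legitimately drop cells that became exactly zero;
    # anything else missing on either side is a key mismatch.
    bad = (merged["_merge"] != "both") & ~(
        (merged["_merge"] == "left_only") & tailpipe)
    if bad.any():
        raise ValueError(
            f"scenario tables do not align: {merged.loc[bad, keys].iloc[0].to_dict()}")
    merged = merged.fillna({"grams_w": 0.0})
    red = merged["grams_wo"] - merged["grams_w"]
    if (red < -1e-9 * merged["grams_wo"].clip(lower=1.0)).any():
        raise ValueError("negative reduction: scenarios inconsistent")
    out = merged[keys].copy()
    out["grams"] = red.clip(lower=0.0)
    return out


def annual_totals(grams: pd.DataFrame | LinkEmissions, links: pd.DataFrame,
                  tracts: pd.DataFrame,
                  days_per_year: int = DAYS_PER_YEAR) -> pd.DataFrame:
    """Tons/year by pollutant × DAC group.

    The link-hour table represents one typical day; annual mass is the day
    total scaled to ``days_per_year`` and converted to metric tons, grouped
    by the DAC flag of the tract containing each link's midpoint.
    """
    df = grams.grams if isinstance(grams, LinkEmissions) else grams
    if len(df) == 0:
        return pd.DataFrame(columns=["pollutant", "group", "tons_per_year"])
    link_tract = links.set_index("link_id")["tract_id"]
    dac = tracts.set_index("tract_id")["dac"]
    out = df.copy()
    out["group"] = np.where(
        dac.reindex(link_tract.reindex(out["link_id"]).to_numpy()).to_numpy(),
        "DAC", "nonDAC")
    totals = (out.groupby(["pollutant", "group"], observed=True)["grams"]
              .sum().mul(days_per_year / GRAMS_PER_TON)
              .rename("tons_per_year").reset_index())
    return totals
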