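"""Synthetic study-region generator.

Builds a square planar region whose statistical structure mirrors the one the
downstream equity analysis assumes: a disadvantage gradient across census
tracts, zero-emission-vehicle (ZEV) ownership negatively coupled to
disadvantage, heavy-truck traffic concentrated on freeway corridors through
high-disadvantage tracts, bimodal diurnal trip departures, and four-season
meteorology.  Every artifact is a deterministic function of the spec seed.

Geometry is a flat square grid in meters — tract polygons are axis-aligned
squares, roads run along tract boundaries, and two freeway corridors cut
through tract interiors.  No geographic projection is involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

YEARS = list(range(2015, 2021))
MONTHS = [1, 4, 7, 10]  # one sampled month per season
TECHNOLOGIES = ["ICEV", "PHEV", "BEV"]
VEHICLE_CLASSES = ["LDV", "MDV", "HDV"]
WEIGHT_CLASSES = ["LDV", "MDV", "HDV", "BUS"]
POLLUTANTS = ["PM2.5", "NOx", "CO2"]
PROCESSES = ["running_exhaust", "start_exhaust", "idling", "brake_tire_wear"]
TAILPIPE_PROCESSES = ["running_exhaust", "start_exhaust", "idling"]
DEMO_GROUPS = ["Hispanic", "White", "AAPI", "AfricanAm", "OtherMult", "NativeAm"]

# County-wide demographic base shares (large urban county, Fig.-style groups).
_DEMO_BASE = np.array([0.48, 0.26, 0.15, 0.08, 0.025, 0.005])

# Free-flow speeds used for shortest-path travel times (km/h).
_SPEED_KMH = {"freeway": 100.0, "arterial": 40.0, "ramp": 40.0}

# Hour-of-day stability-class probabilities (Pasquill A..F), by regime.
# Night hours are predominantly stable (E/F), midday predominantly unstable.
STABILITY_TABLE: Dict[str, List[float]] = {
    "night": [0.00, 0.00, 0.05, 0.25, 0.35, 0.35],
    "transition": [0.02, 0.08, 0.20, 0.50, 0.15, 0.05],
    "midday": [0.15, 0.25, 0.30, 0.25, 0.04, 0.01],
}
_NIGHT_HOURS = set(range(0, 6)) | {22, 23}
_MIDDAY_HOURS = set(range(9, 18))

# Per-month meteorology parameters: (mean wind speed m/s, lognormal sigma,
# prevailing direction deg FROM, direction spread deg, midday instability boost)
_MET_PARAMS = {
    1: (2.4, 0.45, 60.0, 45.0, 0.0),
    4: (3.4, 0.40, 250.0, 35.0, 0.05),
    7: (3.0, 0.35, 260.0, 25.0, 0.12),
    10: (2.7, 0.40, 240.0, 40.0, 0.03),
}


class InvalidSpecError(ValueError):
    """Raised when a RegionSpec violates its invariants."""


@dataclass(frozen=True)
class RegionSpec:
    """Parameters controlling the synthetic region.

    Defaults define the reference study conditions used throughout the test
    suite: a 400-tract, 20 km × 20 km county with a pronounced west-to-east
    disadvantage gradient, ownership disparity, and truck corridors through
    the high-disadvantage band.
    """

    n_tracts: int = 400
    grid_extent_m: float = 20_000.0
    seed: int = 0
    disadvantage_gradient: float = 0.7
    ownership_disparity: float = 1.0
    truck_corridor_bias: float = 0.8
    n_trips: int = 50_000
    fleet_size_per_household: float = 1.8
    met_days: int = 2
    target_year_penetration: float = 0.5
    mean_tract_population: float = 4000.0

    def __post_init__(self) -> None:
        g = math.isqrt(self.n_tracts)
        if self.n_tracts < 4 or g * g != self.n_tracts:
            raise InvalidSpecError(
                f"n_tracts must be a perfect square >= 4, got {self.n_tracts}"
            )
        for name in ("disadvantage_gradient", "truck_corridor_bias",
                     "target_year_penetration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name} must be in [0, 1], got {v}")
        if self.ownership_disparity < 0:
            raise InvalidSpecError("ownership_disparity must be >= 0")
        if self.met_days < 1:
            raise InvalidSpecError("met_days must be >= 1")
        if self.n_trips < 0 or self.grid_extent_m <= 0:
            raise InvalidSpecError("n_trips and grid_extent_m must be positive")

    @property
    def grid_side(self) -> int:
        return math.isqrt(self.n_tracts)

    @property
    def cell_m(self) -> float:
        return self.grid_extent_m / self.grid_side


@dataclass
class SyntheticRegion:
    """Bundle of all generated inputs for one region realization."""

    spec: RegionSpec
    tracts: pd.DataFrame
    links: pd.DataFrame
    trips: pd.DataFrame
    fleet_history: pd.DataFrame
    met: pd.DataFrame
    rates: pd.DataFrame
    weight_map: pd.DataFrame
    skipped_trips: int = 0


def _rng(spec: RegionSpec, stage: int) -> np.random.Generator:
    """Independent, reproducible stream per generation stage."""
    return np.random.default_rng([stage, spec.seed])


def tract_of_point(spec: RegionSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Map planar points to tract row-major indices.

    Containment uses half-open cells [x0, x1) × [y0, y1) so that points on a
    shared boundary belong to exactly one tract; points on the far region
    boundary are clipped into the last cell.
    """
    g, cell = spec.grid_side, spec.cell_m
    col = np.clip(np.floor(np.asarray(x) / cell).astype(int), 0, g - 1)
    row = np.clip(np.floor(np.asarray(y) / cell).astype(int), 0, g - 1)
    return row * g + col


def generate_tracts(spec: RegionSpec) -> pd.DataFrame:
    """Generate the tract grid with population, demographics, and scores.

    The pollution-burden score mixes a deterministic west-to-east gradient
    (weight ``disadvantage_gradient``) with i.i.d. noise, so a zero gradient
    yields spatially uncorrelated scores.  Demographic fractions are tilted
    with burden: the Hispanic and African-American shares grow with burden
    while the White and AAPI shares shrink, mirroring the empirical coupling
    between disadvantage percentile and race/ethnicity.
    """
    rng = _rng(spec, 1)
    g, cell = spec.grid_side, spec.cell_m
    n = spec.n_tracts
    rows, cols = np.divmod(np.arange(n), g)

    population = np.maximum(
        100, np.round(rng.lognormal(np.log(spec.mean_tract_population), 0.35, n))
    ).astype(int)
    households = np.maximum(30, np.round(population / 2.9)).astype(int)

    gx = cols / max(g - 1, 1)  # 0 at west edge, 1 at east edge
    dg = spec.disadvantage_gradient
    burden_raw = dg * gx + (1.0 - dg) * rng.uniform(0.0, 1.0, n)
    burden_raw = burden_raw + 1e-9 * rng.uniform(0.0, 1.0, n)  # break exact ties
    pollution_burden = 10.0 * np.clip(burden_raw, 0.0, 1.0)
    pc_raw = np.clip(0.6 * burden_raw + 0.4 * rng.uniform(0.0, 1.0, n), 0.0, 1.0)
    pop_characteristics = 10.0 * pc_raw

    # Demographic tilt: exponential reweighting of base shares by burden.
    tilt_sign = np.array([+1.0, -1.0, -1.0, +1.0, 0.0, 0.0])
    centred = burden_raw - np.mean(burden_raw)
    weights = _DEMO_BASE[None, :] * np.exp(
        1.6 * tilt_sign[None, :] * centred[:, None]
    )
    conc = 300.0  # Dirichlet-like concentration; higher = less noise
    demo = rng.gamma(np.maximum(conc * weights, 1e-9))
    demo = demo / demo.sum(axis=1, keepdims=True)

    x0, y0 = cols * cell, rows * cell
    tracts = pd.DataFrame(
        {
            "tract_id": [f"T{i:04d}" for i in range(n)],
            "row": rows,
            "col": cols,
            "x0": x0,
            "y0": y0,
            "x1": x0 + cell,
            "y1": y0 + cell,
            "cx": x0 + cell / 2,
            "cy": y0 + cell / 2,
            "population": population,
            "households": households,
            "pollution_burden": pollution_burden,
            "pop_characteristics": pop_characteristics,
        }
    )
    for j, group in enumerate(DEMO_GROUPS):
        tracts[f"frac_{group}"] = demo[:, j]
    return tracts


def _burden_percentile(tracts: pd.DataFrame) -> np.ndarray:
    """Rank-based percentile of the pollution-burden score, in [0, 1]."""
    return rankdata(tracts["pollution_burden"].to_numpy()) / len(tracts)


def generate_network(spec: RegionSpec, tracts: pd.DataFrame) -> pd.DataFrame:
    """Grid of boundary arterials plus two freeway corridors with ramps.

    Arterials run along every tract boundary edge (corner-node lattice).
    Two freeways — one vertical, one horizontal — run through tract
    interiors; with ``truck_corridor_bias > 0`` they are aligned with the
    highest-burden column/row band, otherwise with the region center.
    """
    g, cell = spec.grid_side, spec.cell_m
    records: List[dict] = []

    def node_xy(ix: int, iy: int) -> Tuple[float, float]:
        return ix * cell, iy * cell

    for ix in range(g + 1):
        for iy in range(g + 1):
            if ix < g:
                xa, ya = node_xy(ix, iy)
                xb, yb = node_xy(ix + 1, iy)
                records.append(dict(x1=xa, y1=ya, x2=xb, y2=yb,
                                    road_class="arterial", lanes=2))
            if iy < g:
                xa, ya = node_xy(ix, iy)
                xb, yb = node_xy(ix, iy + 1)
                records.append(dict(x1=xa, y1=ya, x2=xa, y2=yb,
                                    road_class="arterial", lanes=2))

    burden = tracts["pollution_burden"].to_numpy()
    col_mean = np.array([burden[tracts["col"] == c].mean() for c in range(g)])
    row_mean = np.array([burden[tracts["row"] == r].mean() for r in range(g)])
    if spec.truck_corridor_bias > 0:
        col_f, row_f = int(np.argmax(col_mean)), int(np.argmax(row_mean))
    else:
        col_f, row_f = g // 2, g // 2

    # Vertical freeway through the interior of column col_f.
    xf = (col_f + 0.5) * cell
    for iy in range(g):
        records.append(dict(x1=xf, y1=iy * cell, x2=xf, y2=(iy + 1) * cell,
                            road_class="freeway", lanes=4))
    # Horizontal freeway through the interior of row row_f.
    yf = (row_f + 0.5) * cell
    for ix in range(g):
        records.append(dict(x1=ix * cell, y1=yf, x2=(ix + 1) * cell, y2=yf,
                            road_class="freeway", lanes=4))
    # Ramps tie each freeway vertex to the two flanking corner nodes.
    for iy in range(g + 1):
        for dx in (0, 1):
            records.append(dict(x1=xf, y1=iy * cell,
                                x2=(col_f + dx) * cell, y2=iy * cell,
                                road_class="ramp", lanes=1))
    for ix in range(g + 1):
        for dy in (0, 1):
            records.append(dict(x1=ix * cell, y1=yf,
                                x2=ix * cell, y2=(row_f + dy) * cell,
                                road_class="ramp", lanes=1))

    links = pd.DataFrame.from_records(records)
    links.insert(0, "link_id", [f"L{i:05d}" for i in range(len(links))])
    links["length_m"] = np.hypot(links["x2"] - links["x1"],
                                 links["y2"] - links["y1"])
    links = links[links["length_m"] > 0].reset_index(drop=True)
    links["mx"] = (links["x1"] + links["x2"]) / 2
    links["my"] = (links["y1"] + links["y2"]) / 2
    tract_idx = tract_of_point(spec, links["mx"].to_numpy(),
                               links["my"].to_numpy())
    links["tract_id"] = tracts["tract_id"].to_numpy()[tract_idx]
    return links


def _logistic(t: np.ndarray, n0: np.ndarray, k: np.ndarray,
              r: np.ndarray) -> np.ndarray:
    return k / (1.0 + ((k - n0) / n0) * np.exp(-r * t))


def generate_fleet_history(spec: RegionSpec, tracts: pd.DataFrame) -> pd.DataFrame:
    """Per-tract × year × technology fleet counts, 2015-2020.

    Each tract's ZEV count follows a logistic curve whose 2015 level and
    growth rate both decrease with burden percentile in proportion to
    ``ownership_disparity``; the total fleet (households × vehicles per
    household) is constant over the window.  Baseline magnitudes are chosen
    so the county ZEV fleet share is ~0.7% in 2015 growing to ~2% in 2020,
    the scale observed for California light-duty fleets in those years.
    """
    rng = _rng(spec, 2)
    n = len(tracts)
    pct = _burden_percentile(tracts)
    fleet = np.round(
        tracts["households"].to_numpy() * spec.fleet_size_per_household
    ).astype(int)

    # Disparity acts mostly through the starting level; growth rates are
    # only mildly graded, so saturation (and the county rescale) narrows
    # relative disparity by the horizon year, as observed adoption does.
    noise_r = rng.normal(0.0, 0.02, n)
    noise_s = rng.normal(0.0, 0.25, n)
    r = np.clip(0.30 - 0.05 * spec.ownership_disparity * pct + noise_r, 0.05, 1.0)
    s0 = 0.013 * np.exp(-1.5 * spec.ownership_disparity * pct + noise_s)
    s0 = np.clip(s0, 1e-4, 0.3)

    n0 = np.maximum(s0 * fleet, 0.5)
    bev_share = 0.6
    rows = []
    for year in YEARS:
        t = year - YEARS[0]
        zev = np.round(_logistic(float(t), n0, fleet.astype(float), r)).astype(int)
        zev = np.minimum(zev, fleet)
        bev = np.round(bev_share * zev).astype(int)
        phev = zev - bev
        icev = fleet - zev
        for tech, counts in (("ICEV", icev), ("PHEV", phev), ("BEV", bev)):
            rows.append(pd.DataFrame({
                "tract_id": tracts["tract_id"],
                "year": year,
                "tech": tech,
                "count": counts,
            }))
    return pd.concat(rows, ignore_index=True)


def _build_graph(links: pd.DataFrame, truck: bool,
                 truck_bias: float) -> Tuple[csr_matrix, Dict, List]:
    """Sparse travel-time graph over link endpoints.

    For trucks, arterial travel times are inflated by
    ``1 + 8 × truck_corridor_bias`` (ramps exempt, so freeway access stays
    cheap) so heavy vehicles prefer the freeway corridors.
    """
    coords: Dict[Tuple[float, float], int] = {}

    def nid(x: float, y: float) -> int:
        key = (round(x, 6), round(y, 6))
        if key not in coords:
            coords[key] = len(coords)
        return coords[key]

    a_idx, b_idx, w = [], [], []
    edge_link: Dict[Tuple[int, int], int] = {}
    for i, row in enumerate(links.itertuples(index=False)):
        na, nb = nid(row.x1, row.y1), nid(row.x2, row.y2)
        speed = _SPEED_KMH[row.road_class] / 3.6  # m/s
        time = row.length_m / speed
        if truck and row.road_class == "arterial":
            time *= 1.0 + 8.0 * truck_bias
        a_idx += [na, nb]
        b_idx += [nb, na]
        w += [time, time]
        edge_link.setdefault((na, nb), i)
        edge_link.setdefault((nb, na), i)
    nn = len(coords)
    graph = csr_matrix((w, (a_idx, b_idx)), shape=(nn, nn))
    return graph, edge_link, list(coords)


def generate_trips(spec: RegionSpec, tracts: pd.DataFrame,
                   links: pd.DataFrame) -> Tuple[pd.DataFrame, int]:
    """Routed synthetic trip table.

    Light-duty origins are sampled proportional to tract population;
    destinations by a gravity kernel, attraction × exp(−distance / 6 km)
    excluding the origin tract.  Attraction is population tilted toward
    high-burden tracts (employment and industrial activity concentrate
    there), and medium/heavy trucks draw both origins and destinations from
    a more strongly tilted weight scaled by ``truck_corridor_bias`` —
    freight depots sit in the disadvantaged band.  Departure hours follow a
    bimodal AM/PM-peak profile.  Routes are static shortest paths by
    free-flow travel time, with trucks additionally biased onto freeway
    corridors.  Returns (trips, n_skipped) where skipped trips had no path
    between endpoints (impossible on the standard grid).
    """
    rng = _rng(spec, 3)
    n = len(tracts)
    pop = tracts["population"].to_numpy().astype(float)
    cx, cy = tracts["cx"].to_numpy(), tracts["cy"].to_numpy()

    vclass = rng.choice(VEHICLE_CLASSES, size=spec.n_trips,
                        p=[0.94, 0.04, 0.02])
    truck = np.isin(vclass, ["MDV", "HDV"])

    centred = tracts["pollution_burden"].to_numpy() / 10.0
    centred = centred - centred.mean()
    attraction_ldv = pop * np.exp(2.0 * centred)
    attraction_trk = pop * np.exp((2.0 + 2.0 * spec.truck_corridor_bias)
                                  * centred)

    origins = np.empty(spec.n_trips, dtype=int)
    p_ldv = pop / pop.sum()
    p_trk = attraction_trk / attraction_trk.sum()
    origins[~truck] = rng.choice(n, size=int((~truck).sum()), p=p_ldv)
    origins[truck] = rng.choice(n, size=int(truck.sum()), p=p_trk)

    dist = np.hypot(cx[:, None] - cx[None, :], cy[:, None] - cy[None, :])
    decay = np.exp(-dist / 6000.0)
    dests = np.empty(spec.n_trips, dtype=int)
    u = rng.uniform(size=spec.n_trips)
    for attraction, mask in ((attraction_ldv, ~truck),
                             (attraction_trk, truck)):
        grav = attraction[None, :] * decay
        np.fill_diagonal(grav, 0.0)
        cum = np.cumsum(grav / grav.sum(axis=1, keepdims=True), axis=1)
        idx = np.nonzero(mask)[0]
        dests[idx] = [np.searchsorted(cum[origins[i]], u[i]) for i in idx]
    dests = np.minimum(dests, n - 1)

    kind = rng.choice(3, size=spec.n_trips, p=[0.35, 0.35, 0.30])
    hours = np.where(
        kind == 0, rng.normal(8.0, 1.5, spec.n_trips),
        np.where(kind == 1, rng.normal(17.0, 2.0, spec.n_trips),
                 rng.uniform(0.0, 24.0, spec.n_trips)),
    )
    depart_hour = np.floor(np.mod(hours, 24.0)).astype(int)

    # Tract access node = its SW corner; shortest paths via predecessor trees.
    link_ids = links["link_id"].to_numpy()
    paths: Dict[Tuple[int, int, bool], Tuple[str, ...]] = {}
    routes: List[Tuple[str, ...]] = [()] * spec.n_trips
    skipped = 0
    keep = np.ones(spec.n_trips, dtype=bool)
    for truck in (False, True):
        graph, edge_link, coords = _build_graph(
            links, truck, spec.truck_corridor_bias)
        node_of_tract = np.empty(n, dtype=int)
        lookup = {k: v for k, v in zip(coords, range(len(coords)))}
        cell = spec.cell_m
        for ti in range(n):
            key = (round(tracts["x0"].iat[ti], 6), round(tracts["y0"].iat[ti], 6))
            node_of_tract[ti] = lookup[key]
        mask = (vclass == "HDV") == truck
        sources = np.unique(node_of_tract[origins[mask]])
        src_pos = {s: i for i, s in enumerate(sources)}
        dist_m, pred = dijkstra(graph, directed=False, indices=sources,
                                return_predecessors=True)
        for idx in np.nonzero(mask)[0]:
            o, d = origins[idx], dests[idx]
            no, nd = node_of_tract[o], node_of_tract[d]
            ck = (no, nd, truck)
            if ck not in paths:
                prow = pred[src_pos[no]]
                if no != nd and prow[nd] < 0:
                    paths[ck] = None  # type: ignore[assignment]
                else:
                    seq = []
                    cur = nd
                    while cur != no:
                        prev = prow[cur]
                        seq.append(link_ids[edge_link[(prev, cur)]])
                        cur = prev
                    paths[ck] = tuple(reversed(seq))
            route = paths[ck]
            if route is None or len(route) == 0:
                skipped += 1
                keep[idx] = False
                logger.warning("trip %d skipped: no path %s -> %s", idx, o, d)
            else:
                routes[idx] = route

    trips = pd.DataFrame({
        "trip_id": [f"P{i:06d}" for i in range(spec.n_trips)],
        "origin_tract": tracts["tract_id"].to_numpy()[origins],
        "dest_tract": tracts["tract_id"].to_numpy()[dests],
        "vclass": vclass,
        "depart_hour": depart_hour,
        "route": routes,
        "is_zev": False,
    })
    trips = trips[keep].reset_index(drop=True)
    return trips, skipped


def generate_met(spec: RegionSpec) -> pd.DataFrame:
    """Hourly meteorology for ``met_days`` days in each of four months.

    Wind speeds are lognormal with month-specific parameters and floored at
    0.5 m/s; directions are month-prevailing with Gaussian spread (wrapped);
    stability classes are drawn from an hour-of-day table (stable at night,
    unstable midday) with a seasonal midday instability boost.
    """
    rng = _rng(spec, 4)
    rows = []
    classes = np.array(list("ABCDEF"))
    for month in MONTHS:
        ws_mean, ws_sig, dir_mean, dir_sig, boost = _MET_PARAMS[month]
        for day in range(1, spec.met_days + 1):
            for hour in range(24):
                ws = max(0.5, rng.lognormal(np.log(ws_mean), ws_sig))
                wd = float(np.mod(rng.normal(dir_mean, dir_sig), 360.0))
                if hour in _NIGHT_HOURS:
                    probs = np.array(STABILITY_TABLE["night"])
                elif hour in _MIDDAY_HOURS:
                    probs = np.array(STABILITY_TABLE["midday"])
                    probs = probs + boost * np.array([1.0, 0.5, 0, -0.5, -0.5, -0.5])
                    probs = np.maximum(probs, 0.0)
                else:
                    probs = np.array(STABILITY_TABLE["transition"])
                probs = probs / probs.sum()
                stab = rng.choice(classes, p=probs)
                rows.append((month, day, hour, ws, wd, stab))
    return pd.DataFrame(
        rows, columns=["month", "day", "hour", "wind_speed_ms",
                       "wind_dir_deg", "stability_class"])


# Fine vehicle categories per weight class and their fleet shares.
_CATEGORIES = {
    "LDV": [("LDA", 0.70), ("LDT1", 0.30)],
    "MDV": [("MDV1", 0.55), ("MDV2", 0.45)],
    "HDV": [("MHDT", 0.60), ("HHDT", 0.40)],
    "BUS": [("UBUS", 0.50), ("SBUS", 0.50)],
}

# ICEV emission rates by (pollutant, category): running g/mi, start g/start,
# idling g/hour, brake+tire g/mi (brake/tire is particulate only).
_RATES = {
    ("NOx", "LDA"): (0.08, 0.15, 0.5, 0.0),
    ("NOx", "LDT1"): (0.12, 0.20, 0.7, 0.0),
    ("NOx", "MDV1"): (0.40, 0.50, 2.0, 0.0),
    ("NOx", "MDV2"): (0.60, 0.65, 2.5, 0.0),
    ("NOx", "MHDT"): (2.00, 1.50, 8.0, 0.0),
    ("NOx", "HHDT"): (3.50, 2.00, 11.0, 0.0),
    ("NOx", "UBUS"): (2.50, 1.60, 9.0, 0.0),
    ("NOx", "SBUS"): (3.00, 1.80, 10.0, 0.0),
    ("PM2.5", "LDA"): (0.0020, 0.0030, 0.010, 0.012),
    ("PM2.5", "LDT1"): (0.0030, 0.0040, 0.014, 0.014),
    ("PM2.5", "MDV1"): (0.0080, 0.0090, 0.040, 0.020),
    ("PM2.5", "MDV2"): (0.0120, 0.0120, 0.055, 0.025),
    ("PM2.5", "MHDT"): (0.0400, 0.0300, 0.180, 0.035),
    ("PM2.5", "HHDT"): (0.0600, 0.0400, 0.260, 0.040),
    ("PM2.5", "UBUS"): (0.0500, 0.0350, 0.220, 0.035),
    ("PM2.5", "SBUS"): (0.0550, 0.0380, 0.240, 0.038),
    ("CO2", "LDA"): (320.0, 30.0, 1500.0, 0.0),
    ("CO2", "LDT1"): (400.0, 38.0, 1800.0, 0.0),
    ("CO2", "MDV1"): (600.0, 55.0, 2600.0, 0.0),
    ("CO2", "MDV2"): (750.0, 65.0, 3200.0, 0.0),
    ("CO2", "MHDT"): (1400.0, 110.0, 5200.0, 0.0),
    ("CO2", "HHDT"): (1700.0, 130.0, 6200.0, 0.0),
    ("CO2", "UBUS"): (1600.0, 120.0, 5800.0, 0.0),
    ("CO2", "SBUS"): (1650.0, 125.0, 6000.0, 0.0),
}

_UNITS = {"running_exhaust": "g/mile", "start_exhaust": "g/start",
          "idling": "g/hour", "brake_tire_wear": "g/mile"}


def generate_emission_rates(
    spec: RegionSpec,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Emission-rate table and weight-class membership map.

    Rates are fixed EMFAC-like magnitudes per pollutant × fine category ×
    process, for both ICEV and ZEV technology: ZEV rows are zero for the
    three tailpipe processes and carry the same brake/tire-wear rate as
    their ICEV counterpart.
    """
    rows = []
    for (pollutant, cat), (run, start, idle, brake) in _RATES.items():
        by_proc = {"running_exhaust": run, "start_exhaust": start,
                   "idling": idle, "brake_tire_wear": brake}
        for proc in PROCESSES:
            for tech in ("ICEV", "ZEV"):
                rate = by_proc[proc]
                if tech == "ZEV" and proc in TAILPIPE_PROCESSES:
                    rate = 0.0
                rows.append((pollutant, cat, tech, proc, rate, _UNITS[proc]))
    rates = pd.DataFrame(
        rows, columns=["pollutant", "category", "tech", "process",
                       "rate", "units"])

    wm_rows = [(wc, cat, share)
               for wc, members in _CATEGORIES.items()
               for cat, share in members]
    weight_map = pd.DataFrame(
        wm_rows, columns=["weight_class", "category", "vp_share"])
    return rates, weight_map


def validate_region(region: SyntheticRegion) -> None:
    """Cross-artifact invariant checks; raises AssertionError on violation."""
    spec = region.spec
    demo = region.tracts[[f"frac_{g}" for g in DEMO_GROUPS]].to_numpy()
    assert np.allclose(demo.sum(axis=1), 1.0, atol=1e-9), "demo fractions"
    link_set = set(region.links["link_id"])
    for route in region.trips["route"]:
        assert route and all(l in link_set for l in route), "route link refs"
    fh = region.fleet_history
    assert (fh["count"] >= 0).all()
    totals = fh.groupby(["tract_id", "year"])["count"].sum().unstack()
    assert (totals.nunique(axis=1) == 1).all(), "fleet totals vary by year"
    assert (region.met["wind_speed_ms"] >= 0.5).all()
    vp = region.weight_map.groupby("weight_class")["vp_share"].sum()
    assert np.allclose(vp, 1.0, atol=1e-12), "weight-class shares"


def generate_region(spec: RegionSpec) -> SyntheticRegion:
    """Generate every artifact for one seeded region realization."""
    tracts = generate_tracts(spec)
    links = generate_network(spec, tracts)
    fleet = generate_fleet_history(spec, tracts)
    trips, skipped = generate_trips(spec, tracts, links)
    met = generate_met(spec)
    rates, weight_map = generate_emission_rates(spec)
    region = SyntheticRegion(spec=spec, tracts=tracts, links=links,
                             trips=trips, fleet_history=fleet, met=met,
                             rates=rates, weight_map=weight_map,
                             skipped_trips=skipped)
    return region
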