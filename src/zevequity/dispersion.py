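"""Steady-state Gaussian line-source dispersion to receptors.

Each road link is treated as a set of parallel ground-level line sources
(one per lane, offset by the lane width).  The concentration at a receptor
is the line integral of the Gaussian point-source kernel with total
reflection at the ground,

    C(x, y, z) = q / (2 pi u sy sz) * exp(-y^2 / 2 sy^2)
                 * [exp(-(z-H)^2 / 2 sz^2) + exp(-(z+H)^2 / 2 sz^2)],

where x is the downwind distance from the source element, y the crosswind
offset, u the wind speed, H the release height, and the plume spreads
sy(x), sz(x) follow Briggs open-country curves parameterized by Pasquill
stability class.  Receptors upwind of a source element receive zero, and
sources farther than 1,500 m from a receptor are excluded exactly — the
distance beyond which primary traffic PM2.5 and NOx are no longer
detectable above background.

The line integral is evaluated by adaptive trapezoid refinement (node count
doubling until successive estimates agree to 0.1% relative or 1e-6 ug/m^3
absolute).  ``line_concentration`` exposes the scalar path;
``transfer_matrix`` runs the same refinement vectorized over all
(source, receptor) pairs for every met hour and factors the field into
geometry/met transfer coefficients times per-pollutant emission strengths,
which is exact by linearity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from zevequity.assignment import METERS_PER_MILE

logger = logging.getLogger(__name__)

CUTOFF_M = 1500.0
RELEASE_HEIGHT_M = 0.5
RECEPTOR_HEIGHT_M = 1.5
LANE_WIDTH_M = 3.75
WIND_FLOOR_MS = 0.5
G_TO_UG = 1e6

# NOx mass reported as NO2-equivalent; molar volume 24.45 L/mol at 25 C, 1 atm.
_NO2_MOLAR_MASS = 46.01
_MOLAR_VOLUME_L = 24.45

# Briggs open-country plume-spread coefficients by Pasquill class:
# sigma_y = a*x/sqrt(1+0.0001x); sigma_z = c*x*(1+d*x)**e
_SIGMA_Y_A = {"A": 0.22, "B": 0.16, "C": 0.11, "D": 0.08, "E": 0.06,
              "F": 0.04}
_SIGMA_Z = {
    "A": (0.20, 0.0, 0.0),
    "B": (0.12, 0.0, 0.0),
    "C": (0.08, 0.0002, -0.5),
    "D": (0.06, 0.0015, -0.5),
    "E": (0.03, 0.0003, -1.0),
    "F": (0.016, 0.0003, -1.0),
}


@dataclass(frozen=True)
class MetHour:
    """One hour of surface meteorology (wind FROM direction, degrees)."""

    wind_speed_ms: float
    wind_dir_deg: float
    stability_class: str
    month: int = 0
    day: int = 0
    hour: int = 0


@dataclass(frozen=True)
class LineSource:
    """A straight ground-level emitting segment."""

    link_id: str
    x1: float
    y1: float
    x2: float
    y2: float
    q_per_m: float  # g / (m s)
    release_height: float = RELEASE_HEIGHT_M

    @property
    def length(self) -> float:
        return float(np.hypot(self.x2 - self.x1, self.y2 - self.y1))


def sigma_yz(stability: str, x: np.ndarray | float) -> Tuple[np.ndarray, np.ndarray]:
    """Briggs open-country plume spreads (m) at downwind distance x (m)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("downwind distance must be positive")
    if stability not in _SIGMA_Y_A:
        raise ValueError(f"unknown stability class {stability!r}")
    sy = _SIGMA_Y_A[stability] * x / np.sqrt(1.0 + 0.0001 * x)
    c, d, e = _SIGMA_Z[stability]
    sz = c * x if d == 0.0 else c * x * (1.0 + d * x) ** e
    return sy, sz


def _flow_vector(wind_dir_deg: float) -> Tuple[float, float]:
    """Unit vector of the direction the wind blows TOWARD (x=east, y=north)."""
    theta = np.deg2rad((wind_dir_deg + 180.0) % 360.0)
    return float(np.sin(theta)), float(np.cos(theta))


def _floored_speed(u: float) -> float:
    if u < WIND_FLOOR_MS:
        logger.warning("wind speed %.2f m/s below floor; using %.1f",
                       u, WIND_FLOOR_MS)
        return WIND_FLOOR_MS
    return float(u)


def point_contribution(q: float, source: Tuple[float, float, float],
                       receptor: Tuple[float, float, float],
                       met: MetHour) -> float:
    """Concentration (ug/m^3) at a receptor from one point source of q g/s."""
    sx, sy_, h = source
    rx, ry, zr = receptor
    u = _floored_speed(met.wind_speed_ms)
    ux, uy = _flow_vector(met.wind_dir_deg)
    dx, dy = rx - sx, ry - sy_
    down = dx * ux + dy * uy
    if down <= 0.0:
        return 0.0
    cross = dx * uy - dy * ux
    sy, sz = sigma_yz(met.stability_class, down)
    c = (q / (2.0 * np.pi * u * sy * sz)
         * np.exp(-cross ** 2 / (2.0 * sy ** 2))
         * (np.exp(-(zr - h) ** 2 / (2.0 * sz ** 2))
            + np.exp(-(zr + h) ** 2 / (2.0 * sz ** 2))))
    return float(c * G_TO_UG)


def _kernel_batch(px: np.ndarray, py: np.ndarray, rx: np.ndarray,
                  ry: np.ndarray, h: float, zr: float, u: float,
                  ux: float, uy: float, stability: str) -> np.ndarray:
    """Vectorized unit-strength point kernel, ug/m^3 per g/s.

    px, py are source-element coordinates broadcast against receptor
    coordinates rx, ry (any matching shapes).
    """
    dx, dy = rx - px, ry - py
    down = dx * ux + dy * uy
    cross = dx * uy - dy * ux
    out = np.zeros(np.broadcast(px, rx).shape, dtype=float)
    mask = down > 0.0
    if not np.any(mask):
        return out
    d = down[mask]
    sy = _SIGMA_Y_A[stability] * d / np.sqrt(1.0 + 0.0001 * d)
    c, dd, e = _SIGMA_Z[stability]
    sz = c * d if dd == 0.0 else c * d * (1.0 + dd * d) ** e
    val = (1.0 / (2.0 * np.pi * u * sy * sz)
           * np.exp(-cross[mask] ** 2 / (2.0 * sy ** 2))
           * (np.exp(-(zr - h) ** 2 / (2.0 * sz ** 2))
              + np.exp(-(zr + h) ** 2 / (2.0 * sz ** 2))))
    out[mask] = val * G_TO_UG
    return out


def _line_integrals(ex1: np.ndarray, ey1: np.ndarray, ex2: np.ndarray,
                    ey2: np.ndarray, rx: np.ndarray, ry: np.ndarray,
                    met: MetHour, h: float = RELEASE_HEIGHT_M,
                    zr: float = RECEPTOR_HEIGHT_M, rtol: float = 1e-3,
                    atol: float = 1e-6, n0: int = 8,
                    max_nodes: int = 2 ** 16) -> np.ndarray:
    """Adaptive trapezoid line integrals for a batch of segment/receptor pairs.

    Returns ug/m^3 per unit line strength of 1 g/(m s).  Node counts double
    independently until every pair's successive estimates agree to ``rtol``
    relative or ``atol`` absolute.
    """
    u = _floored_speed(met.wind_speed_ms)
    ux, uy = _flow_vector(met.wind_dir_deg)
    stab = met.stability_class
    npair = len(ex1)
    length = np.hypot(ex2 - ex1, ey2 - ey1)

    def trapz(idx: np.ndarray, n: int) -> np.ndarray:
        s = np.linspace(0.0, 1.0, n + 1)
        px = ex1[idx, None] + s[None, :] * (ex2 - ex1)[idx, None]
        py = ey1[idx, None] + s[None, :] * (ey2 - ey1)[idx, None]
        f = _kernel_batch(px, py, rx[idx, None], ry[idx, None],
                          h, zr, u, ux, uy, stab)
        w = np.full(n + 1, 1.0)
        w[0] = w[-1] = 0.5
        return (f * w).sum(axis=1) * length[idx] / n

    result = np.zeros(npair)
    active = np.arange(npair)
    n = n0
    prev = trapz(active, n)
    while len(active):
        n *= 2
        if n > max_nodes:
            raise RuntimeError(
                f"line integral failed to converge for {len(active)} pairs "
                f"at {max_nodes} nodes (met={met})")
        cur = trapz(active, n)
        done = np.abs(cur - prev) < np.maximum(rtol * np.abs(cur), atol)
        result[active[done]] = cur[done]
        active = active[~done]
        prev = cur[~done]
    return result


def line_concentration(source: LineSource,
                       receptor: Tuple[float, float, float] | Sequence[float],
                       met: MetHour, rtol: float = 1e-3, atol: float = 1e-6,
                       max_nodes: int = 2 ** 16) -> float:
    """Concentration (ug/m^3) at one receptor from one line source.

    Receptors beyond the 1,500 m cutoff receive exactly zero.
    """
    rx, ry = float(receptor[0]), float(receptor[1])
    zr = float(receptor[2]) if len(receptor) > 2 else RECEPTOR_HEIGHT_M
    if source.q_per_m == 0.0:
        return 0.0
    if _segment_distance(np.array([source.x1]), np.array([source.y1]),
                         np.array([source.x2]), np.array([source.y2]),
                         np.array([rx]), np.array([ry]))[0] > CUTOFF_M:
        return 0.0
    val = _line_integrals(
        np.array([source.x1]), np.array([source.y1]),
        np.array([source.x2]), np.array([source.y2]),
        np.array([rx]), np.array([ry]), met,
        h=source.release_height, zr=zr, rtol=rtol, atol=atol,
        max_nodes=max_nodes)[0]
    return float(val * source.q_per_m)


def _segment_distance(x1: np.ndarray, y1: np.ndarray, x2: np.ndarray,
                      y2: np.ndarray, px: np.ndarray,
                      py: np.ndarray) -> np.ndarray:
    """Minimum distance from points (px, py) to segments (x1,y1)-(x2,y2)."""
    dx, dy = x2 - x1, y2 - y1
    den = dx * dx + dy * dy
    t = np.where(den > 0, ((px - x1) * dx + (py - y1) * dy)
                 / np.where(den > 0, den, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    return np.hypot(px - (x1 + t * dx), py - (y1 + t * dy))


def make_receptors(tracts: pd.DataFrame,
                   height: float = RECEPTOR_HEIGHT_M) -> pd.DataFrame:
    """One receptor per tract at the tract centroid, at breathing height."""
    return pd.DataFrame({
        "receptor_id": [f"R{i:04d}" for i in range(len(tracts))],
        "x": tracts["cx"].to_numpy(float),
        "y": tracts["cy"].to_numpy(float),
        "z": height,
        "tract_id": tracts["tract_id"].to_numpy(),
    })


def build_sublines(links: pd.DataFrame,
                   lane_width: float = LANE_WIDTH_M) -> pd.DataFrame:
    """Per-lane parallel sub-lines for each link, each carrying 1/lanes of
    the link's emissions."""
    rows = []
    for li, row in enumerate(links.itertuples(index=False)):
        dx, dy = row.x2 - row.x1, row.y2 - row.y1
        norm = float(np.hypot(dx, dy))
        nx, ny = -dy / norm, dx / norm  # unit normal
        lanes = int(row.lanes)
        for lane in range(lanes):
            off = (lane - (lanes - 1) / 2.0) * lane_width
            rows.append((row.link_id, li,
                         row.x1 + off * nx, row.y1 + off * ny,
                         row.x2 + off * nx, row.y2 + off * ny,
                         1.0 / lanes))
    return pd.DataFrame(rows, columns=["link_id", "link_idx", "x1", "y1",
                                       "x2", "y2", "weight"])


@dataclass
class TransferMatrix:
    """Geometry/met transfer coefficients for all in-range pairs.

    ``values[p, m]`` is the concentration (ug/m^3) at the receptor of pair p
    during met hour m per unit link line strength of 1 g/(m s); the source
    lane weight is already folded in.
    """

    link_idx: np.ndarray  # per pair, index into the links frame
    receptor_idx: np.ndarray  # per pair, index into the receptors frame
    values: np.ndarray  # shape (n_pairs, n_met_hours)
    met: pd.DataFrame
    n_receptors: int


def transfer_matrix(links: pd.DataFrame, receptors: pd.DataFrame,
                    met: pd.DataFrame, cutoff: float = CUTOFF_M,
                    lane_width: float = LANE_WIDTH_M,
                    release_height: float = RELEASE_HEIGHT_M) -> TransferMatrix:
    """Evaluate unit-strength line integrals for every in-range pair and hour."""
    subs = build_sublines(links, lane_width)
    sx1, sy1 = subs["x1"].to_numpy(), subs["y1"].to_numpy()
    sx2, sy2 = subs["x2"].to_numpy(), subs["y2"].to_numpy()
    rx, ry = receptors["x"].to_numpy(), receptors["y"].to_numpy()
    zr = float(receptors["z"].iloc[0]) if "z" in receptors else RECEPTOR_HEIGHT_M

    dist = _segment_distance(sx1[:, None], sy1[:, None], sx2[:, None],
                             sy2[:, None], rx[None, :], ry[None, :])
    si, ri = np.nonzero(dist <= cutoff)
    ex1, ey1, ex2, ey2 = sx1[si], sy1[si], sx2[si], sy2[si]
    prx, pry = rx[ri], ry[ri]
    weight = subs["weight"].to_numpy()[si]
    link_idx = subs["link_idx"].to_numpy()[si]

    values = np.empty((len(si), len(met)))
    for m, row in enumerate(met.itertuples(index=False)):
        mh = MetHour(wind_speed_ms=row.wind_speed_ms,
                     wind_dir_deg=row.wind_dir_deg,
                     stability_class=row.stability_class)
        values[:, m] = weight * _line_integrals(
            ex1, ey1, ex2, ey2, prx, pry, mh, h=release_height, zr=zr)
    return TransferMatrix(link_idx=link_idx, receptor_idx=ri, values=values,
                          met=met.reset_index(drop=True),
                          n_receptors=len(receptors))


def hourly_field(sources: Iterable[LineSource], receptors: pd.DataFrame,
                 met_hour: MetHour, cutoff: float = CUTOFF_M) -> np.ndarray:
    """Superposed concentrations (ug/m^3) at every receptor for one hour."""
    rx, ry = receptors["x"].to_numpy(), receptors["y"].to_numpy()
    total = np.zeros(len(receptors))
    for src in sources:
        if src.q_per_m == 0.0:
            continue
        dist = _segment_distance(
            np.full(len(rx), src.x1), np.full(len(rx), src.y1),
            np.full(len(rx), src.x2), np.full(len(rx), src.y2), rx, ry)
        in_range = dist <= cutoff
        if not np.any(in_range):
            continue
        idx = np.nonzero(in_range)[0]
        vals = _line_integrals(
            np.full(len(idx), src.x1), np.full(len(idx), src.y1),
            np.full(len(idx), src.x2), np.full(len(idx), src.y2),
            rx[idx], ry[idx], met_hour, h=src.release_height)
        total[idx] += vals * src.q_per_m
    return total


def concentrations(transfer: TransferMatrix, link_emissions: pd.DataFrame,
                   links: pd.DataFrame,
                   pollutants: Sequence[str] = ("PM2.5", "NOx")) -> pd.DataFrame:
    """Receptor × met-hour concentrations from a link-hour emission table.

    ``link_emissions`` holds grams by (link_id, hour, pollutant) for one
    typical day (processes already summed); each met hour draws the
    emission strength of its hour of day.  Returns a long frame
    (receptor_idx, month, day, hour, pollutant, conc_ugm3).
    """
    link_pos = {lid: i for i, lid in enumerate(links["link_id"])}
    length_m = links["length_m"].to_numpy(float)
    n_links = len(links)

    em = (link_emissions.groupby(["link_id", "hour", "pollutant"],
                                 observed=True)["grams"].sum().reset_index())
    q = {p: np.zeros((n_links, 24)) for p in pollutants}
    for row in em.itertuples(index=False):
        if row.pollutant in q:
            li = link_pos[row.link_id]
            # grams over one hour on the whole link -> g/(m s)
            q[row.pollutant][li, row.hour] += row.grams / (3600.0 * length_m[li])

    met = transfer.met
    hod = met["hour"].to_numpy()
    frames = []
    for pol in pollutants:
        conc = np.zeros((transfer.n_receptors, len(met)))
        for m in range(len(met)):
            strength = q[pol][transfer.link_idx, hod[m]]
            contrib = transfer.values[:, m] * strength
            conc[:, m] = np.bincount(transfer.receptor_idx, weights=contrib,
                                     minlength=transfer.n_receptors)
        df = pd.DataFrame(conc, columns=pd.MultiIndex.from_frame(
            met[["month", "day", "hour"]]))
        df.index.name = "receptor_idx"
        long = df.stack([0, 1, 2], future_stack=True).rename("conc_ugm3").reset_index()
        long["pollutant"] = pol
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


def average_fields(conc: pd.DataFrame, receptors: pd.DataFrame) -> Tuple[
        pd.DataFrame, pd.DataFrame]:
    """Aggregate hourly receptor concentrations to annual averages.

    Daily value = mean of that day's 24 hourly values (a day missing hours
    is an error); the annual average daily concentration is the mean over
    all simulated days.  Tract values are means over the tract's receptors.
    Returns (receptor_annual, tract_annual) frames with columns
    (pollutant, value).
    """
    counts = conc.groupby(["receptor_idx", "pollutant", "month", "day"],
                          observed=True)["hour"].nunique()
    if (counts != 24).any():
        bad = counts[counts != 24].index[0]
        raise ValueError(f"incomplete day in concentration table: {bad}")
    daily = (conc.groupby(["receptor_idx", "pollutant", "month", "day"],
                          observed=True)["conc_ugm3"].mean())
    annual = (daily.groupby(["receptor_idx", "pollutant"]).mean()
              .rename("value").reset_index())
    annual["receptor_id"] = receptors["receptor_id"].to_numpy()[
        annual["receptor_idx"]]
    annual["tract_id"] = receptors["tract_id"].to_numpy()[
        annual["receptor_idx"]]
    tract = (annual.groupby(["tract_id", "pollutant"])["value"].mean()
             .reset_index())
    return annual, tract


def nox_ugm3_to_ppb(c: float | np.ndarray) -> float | np.ndarray:
    """NOx mass concentration (as NO2, ug/m^3) to ppb at 25 C, 1 atm."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be nonnegative")
    out = c * _MOLAR_VOLUME_L / _NO2_MOLAR_MASS
    return float(out) if out.ndim == 0 else out
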