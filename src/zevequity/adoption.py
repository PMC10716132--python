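"""ZEV adoption equity curves and logistic projection.

Two responsibilities:

* Lorenz (concentration) curves of cumulative vehicle ownership against
  cumulative population, with tracts ordered from most to least
  disadvantaged, and summary statistics over them.

* Per-tract logistic growth fitting of historical ZEV counts,

      N(t) = K / (1 + ((K - N0) / N0) * exp(-r t)),

  with the carrying capacity K fixed to the tract's light-duty fleet size,
  N0 anchored at the first observation, and the growth rate r estimated by
  least squares on the count scale.  Projections to a horizon year are then
  rescaled by a single county-wide factor (with per-tract fleet caps and
  proportional redistribution) to hit a target fleet penetration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

R_BOUNDS = (1e-4, 5.0)


@dataclass(frozen=True)
class AdoptionCurve:
    """Fitted logistic adoption trajectory for one tract."""

    N0: float
    K: float
    r: float
    t0: int = 2015
    no_adoption: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.N0 < self.K):
            raise ValueError(f"require 0 < N0 < K, got N0={self.N0}, K={self.K}")
        if self.r <= 0:
            raise ValueError("growth rate must be positive")

    def __call__(self, t: float) -> float:
        return self.K / (1.0 + ((self.K - self.N0) / self.N0)
                         * np.exp(-self.r * t))


@dataclass(frozen=True)
class LorenzCurve:
    """Cumulative ownership vs cumulative population, (0,0) to (1,1)."""

    x: np.ndarray  # cumulative population fraction
    y: np.ndarray  # cumulative ownership fraction
    ordering_key: str = "disadvantage percentile, descending"


def lorenz_curve(tracts: pd.DataFrame, counts: Mapping[str, float] | pd.Series,
                 order_col: str = "ces_percentile") -> LorenzCurve:
    """Lorenz curve with tracts sorted most→least disadvantaged."""
    counts = pd.Series(counts)
    if (counts < 0).any():
        raise ValueError("ownership counts must be nonnegative")
    if counts.sum() <= 0:
        raise ValueError("total ownership must be positive")
    df = tracts[["tract_id", "population", order_col]].copy()
    df["count"] = df["tract_id"].map(counts).fillna(0.0)
    df = df.sort_values(order_col, ascending=False, kind="mergesort")
    x = np.concatenate([[0.0], np.cumsum(df["population"].to_numpy(float))])
    y = np.concatenate([[0.0], np.cumsum(df["count"].to_numpy(float))])
    return LorenzCurve(x=x / x[-1], y=y / y[-1])


def share_of_top_quantile(curve: LorenzCurve, q: float) -> float:
    """Ownership share of the most-disadvantaged q of the population."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    return float(np.interp(q, curve.x, curve.y))


def concentration_index(curve: LorenzCurve) -> float:
    """1 − 2 × area under the curve.

    Positive when the disadvantaged (sorted first) own less than their
    population share; zero on the equality diagonal; in [−1, 1].
    """
    return float(1.0 - 2.0 * np.trapezoid(curve.y, curve.x))


def fit_logistic(years: Sequence[int], counts: Sequence[float],
                 K: float, t0: int = 2015) -> AdoptionCurve:
    """Least-squares logistic fit of ZEV counts with N0 fixed.

    N0 is the first nonzero observation; a tract with an all-zero history
    receives a 0.5-vehicle pseudo-count and is flagged ``no_adoption`` so
    its projection stays near zero.  Only r is free; it is found by bounded
    scalar minimization of the count-scale sum of squared errors.
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(years) < 3:
        raise ValueError("need at least 3 observation years")
    if K <= counts.max():
        raise ValueError("carrying capacity must exceed every observation")
    nonzero = np.nonzero(counts)[0]
    no_adoption = len(nonzero) == 0
    n0 = 0.5 if no_adoption else float(counts[nonzero[0]])
    t = years - t0

    def sse(r: float) -> float:
        pred = K / (1.0 + ((K - n0) / n0) * np.exp(-r * t))
        return float(np.sum((pred - counts) ** 2))

    res = minimize_scalar(sse, bounds=R_BOUNDS, method="bounded",
                          options={"xatol": 1e-12})
    if not np.isfinite(res.x) or not np.isfinite(res.fun):
        raise RuntimeError(f"logistic fit failed: r={res.x}, sse={res.fun}, "
                           f"counts={counts.tolist()}")
    return AdoptionCurve(N0=n0, K=float(K), r=float(res.x), t0=int(t0),
                         no_adoption=no_adoption)


def project_adoption(curve: AdoptionCurve, year: int) -> float:
    """Evaluate the fitted logistic at a calendar year."""
    if year < curve.t0:
        raise ValueError("projection year precedes the curve anchor")
    return float(curve(year - curve.t0))


def rescale_to_penetration(projections: Mapping[str, float] | pd.Series,
                           fleet_totals: Mapping[str, float] | pd.Series,
                           target: float, tol: float = 1e-9) -> pd.Series:
    """Scale tract projections so county penetration equals ``target``.

    A single multiplicative factor is applied to every tract; tracts that
    would exceed their own fleet are capped at it and the shortfall is
    redistributed proportionally among uncapped tracts until the county
    ratio converges.
    """
    if not 0.0 < target <= 1.0:
        raise ValueError(f"target penetration must lie in (0, 1], got {target}")
    proj = pd.Series(projections, dtype=float)
    fleet = pd.Series(fleet_totals, dtype=float).reindex(proj.index)
    if proj.sum() <= 0:
        raise ValueError("total projection must be positive")
    goal = target * fleet.sum()
    if goal > fleet.sum() + tol:
        raise ValueError("target exceeds total fleet")

    scaled = proj.copy()
    capped = pd.Series(False, index=proj.index)
    for _ in range(len(proj) + 1):
        remaining = goal - scaled[capped].sum()
        free = scaled[~capped]
        if free.sum() <= 0:
            break
        factor = remaining / free.sum()
        scaled[~capped] = free * factor
        over = (scaled > fleet) & ~capped
        if not over.any():
            break
        scaled[over] = fleet[over]
        capped |= over
    if abs(scaled.sum() - goal) > tol * max(goal, 1.0):
        raise RuntimeError("rescaling did not converge to the target")
    return scaled


def ownership_per_1000(tracts: pd.DataFrame,
                       counts: Mapping[str, float] | pd.Series) -> pd.Series:
    """Vehicles per 1,000 residents; zero-population tracts are dropped."""
    counts = pd.Series(counts, dtype=float)
    pop = tracts.set_index("tract_id")["population"].reindex(counts.index)
    zero = pop <= 0
    if zero.any():
        logger.warning("excluding %d zero-population tracts", int(zero.sum()))
    return 1000.0 * counts[~zero] / pop[~zero]


def fit_and_project(fleet_history: pd.DataFrame, horizon_year: int,
                    target: float) -> pd.DataFrame:
    """Per-tract logistic projection of ZEV counts with county rescaling.

    Takes the long fleet-history table (tract_id, year, tech, count), fits
    each tract's ZEV total (PHEV + BEV) against years since 2015 with K set
    to the tract fleet size, projects to ``horizon_year``, and rescales to
    the target county penetration.  Returns a tract-indexed frame with
    columns r, projected, scaled, fleet.
    """
    zev = (fleet_history[fleet_history["tech"].isin(["PHEV", "BEV"])]
           .groupby(["tract_id", "year"])["count"].sum().unstack())
    fleet = (fleet_history.groupby(["tract_id", "year"])["count"].sum()
             .unstack().iloc[:, 0])
    years = list(zev.columns)
    rows = {}
    for tract_id, series in zev.iterrows():
        k = float(fleet[tract_id])
        counts = series.to_numpy(float)
        k = max(k, counts.max() + 0.5)  # guard degenerate saturated tracts
        curve = fit_logistic(years, counts, K=k, t0=years[0])
        rows[tract_id] = (curve.r, project_adoption(curve, horizon_year))
    result = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=["r", "projected"])
    result["fleet"] = fleet.reindex(result.index)
    result["scaled"] = rescale_to_penetration(
        result["projected"], result["fleet"], target)
    return result
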