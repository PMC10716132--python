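"""Equity reporting: DAC vs non-DAC and racial/ethnic disparity metrics.

Summarizes the pipeline outputs the way environmental-justice analyses of
vehicle electrification present them: group shares of households, ZEV
ownership, and eVMT; geometric-mean (IQR) exposure statistics by scenario;
absolute and relative concentration reductions; the benefit gap (percent by
which the disadvantaged group's relative benefit falls short); racial and
ethnic apportionment of population, ownership and eVMT; and the two
robustness checks — a paired t-test on with/without concentrations and
Pearson stability correlations across repeated random trip selections.
"""

from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from zevequity.region import DEMO_GROUPS

logger = logging.getLogger(__name__)


def geometric_mean(values: np.ndarray | pd.Series) -> float:
    """Geometric mean excluding exact zeros (their count is logged)."""
    v = np.asarray(values, dtype=float)
    nz = v[v > 0]
    dropped = len(v) - len(nz)
    if dropped:
        logger.info("geometric mean excludes %d zero values", dropped)
    if len(nz) == 0:
        return 0.0
    return float(np.exp(np.mean(np.log(nz))))


def iqr(values: np.ndarray | pd.Series) -> tuple[float, float]:
    """25th and 75th percentiles with linear interpolation."""
    q25, q75 = np.percentile(np.asarray(values, dtype=float), [25, 75])
    return float(q25), float(q75)


def _shares(by_group: Mapping[str, float]) -> Dict[str, float]:
    total = sum(by_group.values())
    if total <= 0:
        logger.warning("zero total; group shares undefined")
        return {g: float("nan") for g in by_group}
    return {g: 100.0 * v / total for g, v in by_group.items()}


def dac_summary(tracts: pd.DataFrame, zev_counts: pd.Series,
                evmt: pd.Series, annual_tons: pd.DataFrame,
                tract_concentrations: Mapping[str, pd.DataFrame]) -> dict:
    """Full DAC vs non-DAC report.

    ``tract_concentrations`` maps scenario label ("with_zev"/"without_zev")
    to a tract-level annual-concentration frame (tract_id, pollutant,
    value).  Exposure statistics are geometric mean with (q25, q75);
    reductions are per-tract without − with, summarized the same way.
    """
    t = tracts.set_index("tract_id")
    groups = {"DAC": t.index[t["dac"]], "nonDAC": t.index[~t["dac"]]}
    for name, idx in groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {name} contains no tracts")

    report: dict = {"shares": {}, "exposure": {}, "reductions": {},
                    "annual_tons": {}, "disparity": {}}
    for metric, series in (("households", t["households"]),
                           ("zev_ownership", pd.Series(zev_counts)),
                           ("evmt", pd.Series(evmt))):
        sums = {g: float(series.reindex(idx).sum())
                for g, idx in groups.items()}
        report["shares"][metric] = _shares(sums)

    if len(annual_tons):
        for pol, sub in annual_tons.groupby("pollutant"):
            report["annual_tons"][pol] = dict(
                zip(sub["group"], sub["tons_per_year"].astype(float)))

    wide = {}
    for scen, frame in tract_concentrations.items():
        wide[scen] = frame.pivot(index="tract_id", columns="pollutant",
                                 values="value")
        report["exposure"][scen] = {}
        for pol in wide[scen].columns:
            report["exposure"][scen][pol] = {}
            for g, idx in groups.items():
                vals = wide[scen][pol].reindex(idx).dropna()
                q25, q75 = iqr(vals)
                report["exposure"][scen][pol][g] = {
                    "geometric_mean": geometric_mean(vals),
                    "q25": q25, "q75": q75}

    if "with_zev" in wide and "without_zev" in wide:
        for pol in wide["without_zev"].columns:
            red = wide["without_zev"][pol] - wide["with_zev"][pol]
            report["reductions"][pol] = {}
            rel_by_group = {}
            for g, idx in groups.items():
                r = red.reindex(idx).dropna()
                base = wide["without_zev"][pol].reindex(idx).dropna()
                q25, q75 = iqr(r)
                rel = relative_reduction(float(r.mean()), float(base.mean()))
                rel_by_group[g] = rel
                report["reductions"][pol][g] = {
                    "geometric_mean": geometric_mean(r),
                    "q25": q25, "q75": q75,
                    "mean_absolute": float(r.mean()),
                    "relative_percent": rel}
            report["disparity"][pol] = benefit_gap(
                rel_by_group["DAC"], rel_by_group["nonDAC"])
    return report


def relative_reduction(reduction: float, baseline: float) -> float:
    """Reduction as a percent of the no-ZEV baseline concentration."""
    if baseline <= 0:
        logger.warning("zero baseline; relative reduction undefined")
        return float("nan")
    return 100.0 * reduction / baseline


def benefit_gap(rel_dac: float, rel_nondac: float) -> float:
    """Percent by which DAC relative benefit falls short of non-DAC.

    Positive when DACs benefit relatively less.
    """
    if rel_nondac == 0:
        logger.warning("non-DAC relative reduction is zero; gap undefined")
        return float("nan")
    return 100.0 * (rel_nondac - rel_dac) / rel_nondac


def racial_shares(tracts: pd.DataFrame, zev_counts: pd.Series,
                  evmt: pd.Series, subset: str | None = None) -> pd.DataFrame:
    """Demographic-group shares of population, ZEV ownership and eVMT.

    Each group's share of a quantity is the fraction-weighted sum over
    tracts divided by the county total.  ``subset`` restricts the sum to
    "DAC" or "nonDAC" tracts.
    """
    t = tracts.set_index("tract_id")
    if subset == "DAC":
        t = t[t["dac"]]
    elif subset == "nonDAC":
        t = t[~t["dac"]]
    elif subset is not None:
        raise ValueError(f"unknown subset {subset!r}")

    quantities = {
        "population_share": t["population"].astype(float),
        "zev_share": pd.Series(zev_counts).reindex(t.index).fillna(0.0),
        "evmt_share": pd.Series(evmt).reindex(t.index).fillna(0.0),
    }
    out = {}
    for qname, qvals in quantities.items():
        total = float(qvals.sum())
        if total <= 0:
            raise ValueError(f"zero county total for {qname}")
        out[qname] = {
            g: float(100.0 * (t[f"frac_{g}"] * qvals).sum() / total)
            for g in DEMO_GROUPS}
    return pd.DataFrame(out)


def paired_t(with_values: Sequence[float],
             without_values: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test on per-tract with/without concentrations."""
    a = np.asarray(with_values, dtype=float)
    b = np.asarray(without_values, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    diff = b - a
    if np.all(diff == 0):
        raise ValueError("degenerate test: all differences are zero")
    res = stats.ttest_1samp(diff, 0.0)
    return float(res.statistic), float(res.pvalue)


def stability_correlation(replicate_reductions: Sequence[pd.Series],
                          dac_flags: pd.Series) -> pd.DataFrame:
    """Pearson r of each replicate's tract reductions against replicate 1.

    Computed separately within DAC and non-DAC tract subsets; a replicate
    with zero variance in a subset yields NaN (logged).
    """
    if len(replicate_reductions) < 2:
        raise ValueError("need at least 2 replicates")
    first = pd.Series(replicate_reductions[0])
    rows: List[dict] = []
    for rep_idx, rep in enumerate(replicate_reductions[1:], start=2):
        rep = pd.Series(rep).reindex(first.index)
        for group, mask in (("DAC", dac_flags), ("nonDAC", ~dac_flags)):
            x = first[mask.reindex(first.index).fillna(False)]
            y = rep[x.index]
            if len(x) < 3:
                raise ValueError(f"group {group} has fewer than 3 tracts")
            if x.std() == 0 or y.std() == 0:
                logger.warning("zero-variance vector in group %s, "
                               "replicate %d", group, rep_idx)
                r = float("nan")
            else:
                r = float(stats.pearsonr(x, y).statistic)
            rows.append({"replicate": rep_idx, "group": group, "pearson_r": r})
    return pd.DataFrame(rows)
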