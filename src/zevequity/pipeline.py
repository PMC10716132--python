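"""End-to-end scenario orchestration.

A *study* fixes the synthetic region (one seed); a *scenario* fixes the
analysis year ("base", 2020-like observed ownership, or "horizon",
2035-like projected ownership) and the ZEV mode.  Every scenario runs the
with-ZEV and without-ZEV (all-combustion baseline) emission and dispersion
branches and reports their difference, so air-quality benefits are always
ZEV-attributable by construction.  The expensive geometry/met transfer
coefficients are shared across scenarios and replicates of the same region.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from zevequity import adoption, assignment, designation, dispersion, emissions
from zevequity import equity
from zevequity.io import write_json, write_region
from zevequity.region import RegionSpec, SyntheticRegion, generate_region

logger = logging.getLogger(__name__)

DISPERSED_POLLUTANTS = ("PM2.5", "NOx")


@dataclass(frozen=True)
class ScenarioSpec:
    """One analysis scenario: year and ZEV penetration mode."""

    year: str = "base"  # "base" (2020-like) or "horizon" (2035-like)
    zev_mode: str = "observed"  # none | observed | projected
    ldv_target: float = 0.5  # county LDV penetration in projected mode
    mdv_fraction: float = 0.005
    hdv_fraction: float = 0.002
    assignment_seed: int = 100
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.year not in ("base", "horizon"):
            raise ValueError(f"unknown year {self.year!r}")
        if self.zev_mode not in ("none", "observed", "projected"):
            raise ValueError(f"unknown zev_mode {self.zev_mode!r}")
        for name in ("ldv_target", "mdv_fraction", "hdv_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


# Default scenario pair mirroring the study design: observed 2020-like
# ownership, and a 2035-like horizon with 50/16/20% LDV/MDV/HDV penetration.
BASE_SCENARIO = ScenarioSpec(year="base", zev_mode="observed",
                             mdv_fraction=0.005, hdv_fraction=0.002)
HORIZON_SCENARIO = ScenarioSpec(year="horizon", zev_mode="projected",
                                ldv_target=0.5, mdv_fraction=0.16,
                                hdv_fraction=0.20)


@dataclass(frozen=True)
class StudyConfig:
    """Full configuration for a study run."""

    region: RegionSpec = field(default_factory=RegionSpec)
    horizon_year: int = 2035
    observed_year: int = 2020
    idle_minutes: float = 1.0
    expansion_factor: float = 1.0
    pce_truck: float = assignment.PCE_TRUCK
    cutoff_m: float = dispersion.CUTOFF_M
    lane_width_m: float = dispersion.LANE_WIDTH_M
    dac_top_fraction: float = 0.25
    dac_burden_top_fraction: float = 0.05


@dataclass
class PreparedRegion:
    """Region plus everything reusable across scenarios."""

    config: StudyConfig
    region: SyntheticRegion
    tracts: pd.DataFrame  # designated
    receptors: pd.DataFrame
    class_rates: pd.DataFrame
    transfer: Optional[dispersion.TransferMatrix] = None

    def ensure_transfer(self) -> dispersion.TransferMatrix:
        if self.transfer is None:
            t0 = time.perf_counter()
            self.transfer = dispersion.transfer_matrix(
                self.region.links, self.receptors, self.region.met,
                cutoff=self.config.cutoff_m,
                lane_width=self.config.lane_width_m)
            logger.info("transfer matrix: %d pairs x %d hours in %.1f s",
                        len(self.transfer.link_idx),
                        self.transfer.values.shape[1],
                        time.perf_counter() - t0)
        return self.transfer


@dataclass
class ScenarioResult:
    """Everything one scenario run produces."""

    scenario: ScenarioSpec
    ldv_fractions: pd.Series
    zev_counts: pd.Series
    evmt: pd.Series
    annual_reduction_tons: pd.DataFrame
    tract_concentrations: Dict[str, pd.DataFrame]
    report: dict


def prepare(config: StudyConfig) -> PreparedRegion:
    """Generate and designate the region; aggregate rate tables."""
    region = generate_region(config.region)
    tracts = designation.designate(
        region.tracts, top_fraction=config.dac_top_fraction,
        burden_top_fraction=config.dac_burden_top_fraction)
    receptors = dispersion.make_receptors(tracts)
    class_rates = emissions.aggregate_rates(region.rates, region.weight_map)
    return PreparedRegion(config=config, region=region, tracts=tracts,
                          receptors=receptors, class_rates=class_rates)


def ldv_ownership(prepared: PreparedRegion,
                  scenario: ScenarioSpec) -> tuple[pd.Series, pd.Series]:
    """(ZEV counts, ownership fractions) per tract for the scenario."""
    fh = prepared.region.fleet_history
    fleet = (fh[fh["year"] == prepared.config.observed_year]
             .groupby("tract_id")["count"].sum())
    if scenario.zev_mode == "none":
        counts = pd.Series(0.0, index=fleet.index)
    elif scenario.zev_mode == "observed":
        counts = (fh[(fh["year"] == prepared.config.observed_year)
                     & fh["tech"].isin(["PHEV", "BEV"])]
                  .groupby("tract_id")["count"].sum()
                  .reindex(fleet.index).fillna(0.0))
    else:  # projected
        proj = adoption.fit_and_project(
            fh, prepared.config.horizon_year, scenario.ldv_target)
        counts = proj["scaled"].reindex(fleet.index)
    fractions = (counts / fleet).clip(0.0, 1.0)
    return counts, fractions


def run_scenario(prepared: PreparedRegion,
                 scenario: ScenarioSpec) -> ScenarioResult:
    """Assign, emit, disperse and report one scenario (with vs without ZEV)."""
    config = prepared.config
    region = prepared.region
    zev_counts, fractions = ldv_ownership(prepared, scenario)

    trips_with = assignment.select_zev_trips(
        region.trips, fractions, scenario.mdv_fraction,
        scenario.hdv_fraction, seed=scenario.assignment_seed)
    trips_without = region.trips.copy()
    trips_without["is_zev"] = False

    evmt = assignment.compute_evmt(trips_with, region.links, prepared.tracts,
                                   config.expansion_factor).miles

    branch: Dict[str, emissions.LinkEmissions] = {}
    for label, trips in (("with_zev", trips_with),
                         ("without_zev", trips_without)):
        volumes = assignment.accumulate_link_volumes(
            trips, region.links, config.expansion_factor, config.pce_truck)
        branch[label] = emissions.compute_link_emissions(
            volumes, trips, prepared.class_rates, region.links,
            scenario=label, idle_minutes=config.idle_minutes,
            expansion_factor=config.expansion_factor)

    reductions = emissions.scenario_difference(branch["without_zev"],
                                               branch["with_zev"])
    annual_reduction = emissions.annual_totals(reductions, region.links,
                                               prepared.tracts)

    transfer = prepared.ensure_transfer()
    tract_conc: Dict[str, pd.DataFrame] = {}
    receptor_hourly: Dict[str, pd.DataFrame] = {}
    for label, em in branch.items():
        conc = dispersion.concentrations(transfer, em.grams, region.links,
                                         pollutants=DISPERSED_POLLUTANTS)
        receptor_hourly[label] = conc
        _, tract = dispersion.average_fields(conc, prepared.receptors)
        nox = tract["pollutant"] == "NOx"
        tract.loc[nox, "value"] = dispersion.nox_ugm3_to_ppb(
            tract.loc[nox, "value"].to_numpy())
        tract_conc[label] = tract

    report = equity.dac_summary(prepared.tracts, zev_counts, evmt,
                                annual_reduction, tract_conc)
    report["racial_shares"] = {}
    for subset in (None, "DAC", "nonDAC"):
        try:
            report["racial_shares"][subset or "all"] = equity.racial_shares(
                prepared.tracts, zev_counts, evmt, subset=subset).to_dict()
        except ValueError as exc:  # e.g. zero ZEV total in a null scenario
            report["racial_shares"][subset or "all"] = {"undefined": str(exc)}

    report["tests"] = {}
    for pol in DISPERSED_POLLUTANTS:
        w = tract_conc["with_zev"].query("pollutant == @pol")
        wo = tract_conc["without_zev"].query("pollutant == @pol")
        merged = w.merge(wo, on="tract_id", suffixes=("_w", "_wo"))
        try:
            t, p = equity.paired_t(merged["value_w"], merged["value_wo"])
            report["tests"][f"paired_t_{pol}"] = {"t": t, "p": p}
        except ValueError as exc:
            report["tests"][f"paired_t_{pol}"] = {"degenerate": str(exc)}

    if scenario.replicates > 1:
        report["tests"]["stability"] = _stability(
            prepared, scenario, transfer, tract_conc["without_zev"])

    return ScenarioResult(scenario=scenario, ldv_fractions=fractions,
                          zev_counts=zev_counts, evmt=evmt,
                          annual_reduction_tons=annual_reduction,
                          tract_concentrations=tract_conc, report=report)


def _tract_reduction(prepared: PreparedRegion,
                     transfer: dispersion.TransferMatrix,
                     trips_with: pd.DataFrame, without_tract: pd.DataFrame,
                     pollutant: str) -> pd.Series:
    config = prepared.config
    region = prepared.region
    volumes = assignment.accumulate_link_volumes(
        trips_with, region.links, config.expansion_factor, config.pce_truck)
    em = emissions.compute_link_emissions(
        volumes, trips_with, prepared.class_rates, region.links,
        scenario="with_zev", idle_minutes=config.idle_minutes,
        expansion_factor=config.expansion_factor)
    conc = dispersion.concentrations(transfer, em.grams, region.links,
                                     pollutants=(pollutant,))
    _, tract = dispersion.average_fields(conc, prepared.receptors)
    with_vals = tract.set_index("tract_id")["value"]
    wo = without_tract.query("pollutant == @pollutant")
    wo_vals = wo.set_index("tract_id")["value"]
    if pollutant == "NOx":
        wo_vals = wo_vals / (dispersion._MOLAR_VOLUME_L / dispersion._NO2_MOLAR_MASS)
    return wo_vals - with_vals


def _stability(prepared: PreparedRegion, scenario: ScenarioSpec,
               transfer: dispersion.TransferMatrix,
               without_tract: pd.DataFrame) -> dict:
    """Repeat the random ZEV selection and correlate tract reductions."""
    region = prepared.region
    _, fractions = ldv_ownership(prepared, scenario)
    out = {}
    for pol in DISPERSED_POLLUTANTS:
        reductions: List[pd.Series] = []
        for i in range(scenario.replicates):
            trips_i = assignment.select_zev_trips(
                region.trips, fractions, scenario.mdv_fraction,
                scenario.hdv_fraction, seed=scenario.assignment_seed + i)
            reductions.append(_tract_reduction(
                prepared, transfer, trips_i, without_tract, pol))
        dac = prepared.tracts.set_index("tract_id")["dac"]
        table = equity.stability_correlation(reductions, dac)
        out[pol] = {
            g: float(table[table["group"] == g]["pearson_r"].mean())
            for g in ("DAC", "nonDAC")}
    return out


def compare_scenarios(report_a: dict, report_b: dict) -> dict:
    """Differences of exposure statistics and DAC gaps between two reports."""
    diff: dict = {"exposure_geomean_diff": {}, "gap": {}}
    for scen in report_a["exposure"]:
        if scen not in report_b["exposure"]:
            raise ValueError(f"scenario {scen} missing from second report")
        diff["exposure_geomean_diff"][scen] = {}
        for pol in report_a["exposure"][scen]:
            if pol not in report_b["exposure"][scen]:
                raise ValueError(f"pollutant {pol} missing from second report")
            d = {}
            for g in ("DAC", "nonDAC"):
                a = report_a["exposure"][scen][pol][g]["geometric_mean"]
                b = report_b["exposure"][scen][pol][g]["geometric_mean"]
                d[g] = b - a
            diff["exposure_geomean_diff"][scen][pol] = d
            gap_a = (report_a["exposure"][scen][pol]["DAC"]["geometric_mean"]
                     - report_a["exposure"][scen][pol]["nonDAC"]["geometric_mean"])
            gap_b = (report_b["exposure"][scen][pol]["DAC"]["geometric_mean"]
                     - report_b["exposure"][scen][pol]["nonDAC"]["geometric_mean"])
            diff["gap"].setdefault(scen, {})[pol] = {
                "first": gap_a, "second": gap_b, "change": gap_b - gap_a}
    return diff


def run_study(config: StudyConfig,
              scenarios: Optional[List[ScenarioSpec]] = None,
              outdir: Optional[Path] = None) -> dict:
    """Run the base and horizon scenarios and compare them."""
    if scenarios is None:
        scenarios = [BASE_SCENARIO, HORIZON_SCENARIO]
    t_start = time.perf_counter()
    prepared = prepare(config)
    results = {}
    timings = {"prepare": time.perf_counter() - t_start}
    for scen in scenarios:
        t0 = time.perf_counter()
        results[scen.year] = run_scenario(prepared, scen)
        timings[scen.year] = time.perf_counter() - t0
        logger.info("scenario %s: %.1f s", scen.year, timings[scen.year])

    study: dict = {"reports": {y: r.report for y, r in results.items()},
                   "timings_s": timings}
    if "base" in results and "horizon" in results:
        study["comparison"] = compare_scenarios(
            results["base"].report, results["horizon"].report)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = write_region(prepared.region, outdir)
        paths.update(_write_results(prepared, results, outdir))
        # timings are run metadata, not results: they go in the manifest so
        # identical configs reproduce byte-identical reports
        written = {k: v for k, v in study.items() if k != "timings_s"}
        write_json(written, outdir / "equity_report.json")
        manifest = build_manifest(config, scenarios, paths, timings,
                                  outdir / "equity_report.json")
        write_json(manifest, outdir / "manifest.json")
    study["_results"] = results
    return study


def _write_results(prepared: PreparedRegion,
                   results: Dict[str, "ScenarioResult"],
                   outdir: Path) -> Dict[str, Path]:
    """Tabular result artifacts alongside the nested JSON report."""
    from zevequity import adoption as _ad

    paths: Dict[str, Path] = {}
    paths["receptors"] = outdir / "receptors.csv"
    prepared.receptors.to_csv(paths["receptors"], index=False)

    fh = prepared.region.fleet_history
    lorenz_rows = []
    for tech in ("ICEV", "PHEV", "BEV"):
        counts = (fh[(fh["year"] == 2020) & (fh["tech"] == tech)]
                  .set_index("tract_id")["count"])
        if counts.sum() > 0:
            curve = _ad.lorenz_curve(prepared.tracts, counts)
            lorenz_rows.append(pd.DataFrame(
                {"tech": tech, "cum_population": curve.x,
                 "cum_ownership": curve.y}))
    if lorenz_rows:
        paths["lorenz_points"] = outdir / "lorenz_points.csv"
        pd.concat(lorenz_rows, ignore_index=True).to_csv(
            paths["lorenz_points"], index=False)

    proj, evmt, conc, tons = [], [], [], []
    for year, res in results.items():
        proj.append(pd.DataFrame({
            "tract_id": res.zev_counts.index, "scenario": year,
            "tech": "ZEV", "count": res.zev_counts.to_numpy(),
            "ownership_fraction": res.ldv_fractions.reindex(
                res.zev_counts.index).to_numpy()}))
        evmt.append(res.evmt.rename("evmt_miles").reset_index()
                    .assign(scenario=year))
        tons.append(res.annual_reduction_tons.assign(scenario=year))
        for branch, frame in res.tract_concentrations.items():
            conc.append(frame.assign(scenario=year, branch=branch))
    for name, frames in (("adoption_projection", proj),
                         ("evmt_by_tract", evmt),
                         ("annual_totals", tons),
                         ("concentrations_annual", conc)):
        paths[name] = outdir / f"{name}.csv"
        pd.concat(frames, ignore_index=True).to_csv(paths[name], index=False)
    return paths


def build_manifest(config: StudyConfig, scenarios: List[ScenarioSpec],
                   paths: Dict[str, Path], timings: Dict[str, float],
                   report_path: Path) -> dict:
    from zevequity.io import file_checksum

    cfg = {"study": asdict(config), "scenarios": [asdict(s) for s in scenarios]}
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return {
        "config": cfg,
        "config_hash": cfg_hash,
        "seed": config.region.seed,
        "wall_clock_s": timings,
        "checksums": {name: file_checksum(p) for name, p in paths.items()},
        "report_checksum": file_checksum(report_path),
    }
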