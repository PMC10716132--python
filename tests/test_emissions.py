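"""Rate aggregation and process-resolved link emissions."""

import numpy as np
import pandas as pd
import pytest

from zevequity.assignment import (METERS_PER_MILE, accumulate_link_volumes,
                                  select_zev_trips)
from zevequity.emissions import (LinkEmissions, aggregate_rates, annual_totals,
                                 compute_link_emissions, scenario_difference)
from zevequity.region import PROCESSES, generate_emission_rates, RegionSpec


def _rates(rows):
    return pd.DataFrame(rows, columns=["pollutant", "category", "tech",
                                       "process", "rate"])


def _wmap(rows):
    return pd.DataFrame(rows, columns=["weight_class", "category", "vp_share"])


def test_weighted_rate_is_dot_product():
    rates = _rates([("NOx", "a", "ICEV", "running_exhaust", 1.0),
                    ("NOx", "b", "ICEV", "running_exhaust", 3.0)])
    wm = _wmap([("LDV", "a", 0.25), ("LDV", "b", 0.75)])
    out = aggregate_rates(rates, wm)
    assert out["rate"].iloc[0] == pytest.approx(2.5)


def test_single_category_passthrough_and_convexity():
    rates = _rates([("NOx", "solo", "ICEV", "idling", 7.0)])
    wm = _wmap([("HDV", "solo", 1.0)])
    assert aggregate_rates(rates, wm)["rate"].iloc[0] == 7.0

    rng = np.random.default_rng(12)
    for _ in range(25):
        vals = rng.uniform(0, 10, 3)
        shares = rng.dirichlet(np.ones(3))
        rates = _rates([("PM2.5", f"c{i}", "ICEV", "running_exhaust", v)
                        for i, v in enumerate(vals)])
        wm = _wmap([("LDV", f"c{i}", s) for i, s in enumerate(shares)])
        r = aggregate_rates(rates, wm)["rate"].iloc[0]
        assert vals.min() - 1e-12 <= r <= vals.max() + 1e-12
        assert r == pytest.approx(float(vals @ shares), abs=1e-12)


def test_empty_weight_class_rejected():
    rates = _rates([("NOx", "a", "ICEV", "running_exhaust", 1.0)])
    wm = _wmap([("LDV", "a", 1.0), ("HDV", "ghost", 1.0)])
    with pytest.raises(ValueError):
        aggregate_rates(rates, wm)


def _one_link():
    return pd.DataFrame({
        "link_id": ["L1"], "x1": [0.0], "y1": [0.0],
        "x2": [METERS_PER_MILE], "y2": [0.0],
        "length_m": [METERS_PER_MILE], "road_class": ["arterial"],
        "lanes": [2], "mx": [METERS_PER_MILE / 2], "my": [0.0],
        "tract_id": ["A"],
    })


def _class_rates(running=0.01, brake=0.002, start=0.1, idle=0.6):
    rows = []
    for proc, icev in (("running_exhaust", running),
                       ("start_exhaust", start), ("idling", idle),
                       ("brake_tire_wear", brake)):
        zev = brake if proc == "brake_tire_wear" else 0.0
        rows.append(("LDV", "PM2.5", "ICEV", proc, icev))
        rows.append(("LDV", "PM2.5", "ZEV", proc, zev))
    return pd.DataFrame(rows, columns=["weight_class", "pollutant", "tech",
                                       "process", "rate"])


def _trips(n, zev=0):
    return pd.DataFrame([
        dict(trip_id=f"t{i}", origin_tract="A", dest_tract="A",
             vclass="LDV", depart_hour=9, route=("L1",), is_zev=i < zev)
        for i in range(n)])


def test_running_emission_hand_case():
    trips = _trips(100)
    links = _one_link()
    vol = accumulate_link_volumes(trips, links)
    em = compute_link_emissions(vol, trips, _class_rates(), links,
                                scenario="without_zev")
    g = em.grams.set_index("process")["grams"]
    assert g["running_exhaust"] == pytest.approx(1.0)  # 100 veh x 1 mi x 0.01
    assert g["brake_tire_wear"] == pytest.approx(0.2)
    assert g["start_exhaust"] == pytest.approx(10.0)  # 100 starts x 0.1 g
    assert g["idling"] == pytest.approx(1.0)  # 100 x 0.6 g/h x 1 min


def test_all_zev_zeroes_tailpipe_keeps_brake():
    trips = _trips(100, zev=100)
    links = _one_link()
    vol = accumulate_link_volumes(trips, links)
    em = compute_link_emissions(vol, trips, _class_rates(), links,
                                scenario="with_zev")
    g = em.grams.groupby("process")["grams"].sum()
    assert g["running_exhaust"] == 0.0
    assert g["start_exhaust"] == 0.0
    assert g["idling"] == 0.0
    assert g["brake_tire_wear"] == pytest.approx(0.2)


def test_with_zev_never_exceeds_without():
    trips = _trips(100, zev=40)
    links = _one_link()
    vol = accumulate_link_volumes(trips, links)
    rates = _class_rates()
    w = compute_link_emissions(vol, trips, rates, links, "with_zev")
    wo = compute_link_emissions(vol, trips, rates, links, "without_zev")
    merged = wo.grams.merge(w.grams, on=["link_id", "hour", "pollutant",
                                         "process"], suffixes=("_wo", "_w"))
    assert (merged["grams_wo"] >= merged["grams_w"] - 1e-12).all()


def test_scenario_difference_hand_case():
    trips = _trips(100, zev=100)
    links = _one_link()
    vol = accumulate_link_volumes(trips, links)
    rates = _class_rates()
    w = compute_link_emissions(vol, trips, rates, links, "with_zev")
    wo = compute_link_emissions(vol, trips, rates, links, "without_zev")
    red = scenario_difference(wo, w).set_index("process")["grams"]
    assert red["running_exhaust"] == pytest.approx(1.0)
    assert red["brake_tire_wear"] == 0.0
    same = scenario_difference(wo, wo)
    assert np.allclose(same["grams"], 0.0)


def test_annual_totals_calendar_scaling():
    grams = pd.DataFrame([("L1", 9, "PM2.5", "running_exhaust", 1.0)],
                         columns=["link_id", "hour", "pollutant", "process",
                                  "grams"])
    links = _one_link()
    tracts = pd.DataFrame({"tract_id": ["A"], "dac": [True]})
    out = annual_totals(grams, links, tracts)
    assert out["tons_per_year"].iloc[0] == pytest.approx(3.65e-4)
    assert out["group"].iloc[0] == "DAC"


def test_annual_totals_partition(small_region, designated_tracts):
    trips = select_zev_trips(
        small_region.trips,
        pd.Series(0.3, index=small_region.tracts["tract_id"]), 0.1, 0.1,
        seed=2)
    vol = accumulate_link_volumes(trips, small_region.links)
    class_rates = aggregate_rates(small_region.rates,
                                  small_region.weight_map)
    em = compute_link_emissions(vol, trips, class_rates, small_region.links,
                                "with_zev")
    out = annual_totals(em, small_region.links, designated_tracts)
    by_group = out.groupby("pollutant")["tons_per_year"].sum()
    total = (em.grams.groupby("pollutant")["grams"].sum() * 365 / 1e6)
    for pol in total.index:
        assert by_group[pol] == pytest.approx(total[pol], rel=1e-9)


def per_trip_oracle(trips, links, class_rates, scenario,
                    idle_minutes=1.0, expansion=1.0):
    """Independent per-trip recomputation of total grams by pollutant."""
    length_mi = (links.set_index("link_id")["length_m"]
                 / METERS_PER_MILE).to_dict()
    lookup = class_rates.set_index(
        ["weight_class", "pollutant", "tech", "process"])["rate"].to_dict()
    pollutants = sorted(class_rates["pollutant"].unique())
    totals = {}
    route_mi = {tid: sum(length_mi[l] for l in r)
                for tid, r in zip(trips["trip_id"], trips["route"])}
    for trip in trips.itertuples(index=False):
        zev = trip.is_zev and scenario == "with_zev"
        tech = "ZEV" if zev else "ICEV"
        mi = route_mi[trip.trip_id]
        for pol in pollutants:
            g = (mi * lookup[(trip.vclass, pol, tech, "running_exhaust")]
                 + mi * lookup[(trip.vclass, pol, tech, "brake_tire_wear")]
                 + lookup[(trip.vclass, pol, tech, "start_exhaust")]
                 + lookup[(trip.vclass, pol, tech, "idling")]
                 * idle_minutes / 60.0)
            totals[pol] = totals.get(pol, 0.0) + g * expansion
    return totals


def test_mass_conservation_against_per_trip_oracle(small_region):
    trips = select_zev_trips(
        small_region.trips.head(500),
        pd.Series(0.4, index=small_region.tracts["tract_id"]), 0.2, 0.2,
        seed=3)
    class_rates = aggregate_rates(small_region.rates,
                                  small_region.weight_map)
    for scenario in ("with_zev", "without_zev"):
        vol = accumulate_link_volumes(trips, small_region.links)
        em = compute_link_emissions(vol, trips, class_rates,
                                    small_region.links, scenario)
        got = em.grams.groupby("pollutant")["grams"].sum()
        want = per_trip_oracle(trips, small_region.links, class_rates,
                               scenario)
        for pol, val in want.items():
            assert got[pol] == pytest.approx(val, rel=1e-9)


def test_generated_rate_table_has_all_processes():
    rates, _ = generate_emission_rates(RegionSpec(n_tracts=4))
    counts = rates.groupby(["pollutant", "category", "tech"])["process"].nunique()
    assert (counts == len(PROCESSES)).all()
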