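import itertools

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from oracles import fisher_oracle

from hmisaccess.classify import (
    DegenerateTableError,
    classify_all,
    classify_facility,
    class_distribution,
    fisher_exact,
    operational,
    ownership_type_table,
    percent_providing,
    provision_cube,
)
from hmisaccess.config import INDICATORS, YEARS, RegionConfig
from hmisaccess.hmis_io import UnknownReferenceError
from hmisaccess.synthetic import (
    generate_districts,
    generate_facilities,
    generate_region,
    generate_service_histories,
)


def _registry(rows):
    return pd.DataFrame(
        rows, columns=["facility_id", "name", "type", "ownership", "district_id", "x", "y"]
    )


def _records(rows):
    return pd.DataFrame(rows, columns=["facility_id", "year", "indicator", "count"])


# ---------------------------------------------------------------------------
# provision cube
# ---------------------------------------------------------------------------

def test_provided_iff_count_positive():
    reg = _registry([["f1", "A", "CHPS", "Government", "D01", 0, 0]])
    rec = _records([["f1", 2016, "malaria", 0], ["f1", 2017, "malaria", 1]])
    cube = provision_cube(rec, reg)
    assert not bool(cube.sel(facility="f1", year=2016, indicator="malaria"))
    assert bool(cube.sel(facility="f1", year=2017, indicator="malaria"))


def test_absent_facility_is_all_false_and_never_operational():
    reg = _registry(
        [["f1", "A", "CHPS", "Government", "D01", 0, 0],
         ["f2", "B", "CHPS", "Government", "D01", 0, 0]]
    )
    rec = _records([["f1", 2016, "malaria", 1]])
    cube = provision_cube(rec, reg)
    assert not cube.sel(facility="f2").any()
    assert not operational(cube).sel(facility="f2").any()


def test_unknown_facility_in_records_raises():
    reg = _registry([["f1", "A", "CHPS", "Government", "D01", 0, 0]])
    rec = _records([["ghost", 2016, "malaria", 1]])
    with pytest.raises(UnknownReferenceError, match="ghost"):
        provision_cube(rec, reg)


def test_cube_complete_over_registry_years_indicators(small_region):
    cube = provision_cube(small_region.records, small_region.registry)
    assert cube.shape == (len(small_region.registry), len(YEARS), len(INDICATORS))


# ---------------------------------------------------------------------------
# percent providing
# ---------------------------------------------------------------------------

def test_percent_providing_simple_arithmetic():
    reg = _registry(
        [[f"f{i}", "A", "CHPS", "Government", "D01", 0, 0] for i in range(4)]
    )
    rows = [[f"f{i}", 2016, "outpatient", 1] for i in range(4)]
    rows += [["f0", 2016, "antenatal", 2], ["f1", 2016, "antenatal", 9]]
    cube = provision_cube(_records(rows), reg)
    assert percent_providing(cube, reg, 2016, "antenatal", "CHPS") == pytest.approx(50.0)
    assert percent_providing(cube, reg, 2016, "outpatient") == pytest.approx(100.0)


def test_percent_providing_zero_denominator_warns_nan():
    reg = _registry([["f1", "A", "CHPS", "Government", "D01", 0, 0]])
    cube = provision_cube(_records([]), reg)
    with pytest.warns(UserWarning):
        assert np.isnan(percent_providing(cube, reg, 2016, "outpatient"))


def test_caesarean_rate_uses_hospital_denominator_only():
    reg = _registry(
        [["h1", "A", "Hospital", "Government", "D01", 0, 0],
         ["h2", "B", "Hospital", "Government", "D01", 0, 0],
         ["c1", "C", "CHPS", "Government", "D01", 0, 0]]
    )
    rows = [["h1", 2016, "caesarean", 5], ["h1", 2016, "outpatient", 5],
            ["h2", 2016, "outpatient", 3], ["c1", 2016, "outpatient", 9]]
    cube = provision_cube(_records(rows), reg)
    # 1 of the 2 operational hospitals; the operational CHPS is ineligible
    assert percent_providing(cube, reg, 2016, "caesarean") == pytest.approx(50.0)


def test_percent_providing_matches_independent_tally(small_region):
    """Brute-force group-by recount over a synthetic fixture."""
    cube = provision_cube(small_region.records, small_region.registry)
    reg = small_region.registry
    pos = small_region.records[small_region.records["count"] > 0]
    merged = pos.merge(reg[["facility_id", "type"]], on="facility_id")
    for year in YEARS:
        yr = merged[merged["year"] == year]
        op_ids = set(yr["facility_id"])
        for indicator in INDICATORS:
            for ftype in ["CHPS", "Hospital", None]:
                if indicator == "caesarean" and ftype != "Hospital":
                    continue
                sub = yr if ftype is None else yr[yr["type"] == ftype]
                denom_ids = set(sub["facility_id"])
                num = sub[sub["indicator"] == indicator]["facility_id"].nunique()
                expected = 100.0 * num / len(denom_ids) if denom_ids else np.nan
                with np.errstate(invalid="ignore"):
                    import warnings

                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        got = percent_providing(cube, reg, year, indicator, ftype)
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected)


# ---------------------------------------------------------------------------
# functional classification
# ---------------------------------------------------------------------------

def _history(sets_per_year):
    """Build a year x indicator history from per-year indicator sets."""
    data = np.zeros((len(YEARS), len(INDICATORS)), dtype=bool)
    for yi, s in enumerate(sets_per_year):
        for ind in s:
            data[yi, INDICATORS.index(ind)] = True
    return xr.DataArray(
        data, dims=("year", "indicator"),
        coords={"year": list(YEARS), "indicator": list(INDICATORS)},
    )


@pytest.mark.parametrize(
    "sets, expected",
    [
        ([{"outpatient"}] * 7, "existing_unchanged"),
        ([{"outpatient"}] * 6 + [{"outpatient", "antenatal"}], "existing_increased"),
        ([{"outpatient", "antenatal"}] + [{"outpatient"}] * 6, "existing_decreased"),
        ([{"outpatient"}] * 3 + [{"malaria"}] + [{"outpatient"}] * 3, "existing_varying"),
        ([{"antenatal"}] + [{"antenatal"}] * 5 + [{"birth"}], "existing_varying"),
        ([set(), set(), {"malaria"}, {"malaria"}, set(), set(), set()], "oscillating"),
        ([set()] * 7, "no_service"),
        ([{"malaria"}] + [set()] * 6, "closed"),
        ([set()] * 6 + [{"malaria"}], "newly_operational"),
        ([{"malaria"}] + [set()] * 5 + [{"malaria"}], "other_intermittent"),
    ],
)
def test_classify_rules(sets, expected):
    assert classify_facility(_history(sets)) == expected


def _reference_top_level(pattern):
    """Independent rule table over a 7-bit operational pattern."""
    if not any(pattern):
        return "no_service"
    if pattern[0] and not pattern[6]:
        return "closed"
    if not pattern[0] and pattern[6]:
        return "newly_operational"
    if not pattern[0] and not pattern[6]:
        return "oscillating"
    return "existing" if all(pattern) else "other_intermittent"


def test_all_128_operational_patterns_get_exactly_one_class():
    """Exhaustive enumeration over the 2^7 yearly presence patterns."""
    for bits in itertools.product([False, True], repeat=7):
        sets = [{"outpatient"} if b else set() for b in bits]
        got = classify_facility(_history(sets))
        top = "existing" if got.startswith("existing_") else got
        assert top == _reference_top_level(bits)


def test_classifier_recovers_synthetic_archetypes_exactly():
    cfg = RegionConfig(n_rows=60, n_cols=60, n_facilities=300, seed=21)
    districts = generate_districts(cfg)
    registry, _ = generate_facilities(cfg, districts)
    records, truth = generate_service_histories(registry, cfg)
    classes = classify_all(provision_cube(records, registry))
    aligned = classes.loc[truth["facility_id"]].to_numpy()
    assert (aligned == truth["archetype"].to_numpy()).all()


def test_class_distribution_partitions_registry(small_region):
    cube = provision_cube(small_region.records, small_region.registry)
    classes = classify_all(cube)
    dist = class_distribution(classes, small_region.registry)
    overall = dist[dist["facility_type"] == "all"]
    assert overall["count"].sum() == len(small_region.registry)
    assert overall["percent"].sum() == pytest.approx(100.0, abs=0.1)


def test_single_facility_distribution_is_100_percent():
    reg = _registry([["f1", "A", "CHPS", "Government", "D01", 0, 0]])
    classes = pd.Series({"f1": "no_service"}, name="functional_class")
    dist = class_distribution(classes, reg)
    row = dist[(dist["facility_type"] == "all") & (dist["functional_class"] == "no_service")]
    assert row["percent"].iloc[0] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# ownership x type composition
# ---------------------------------------------------------------------------

def _composition_registry(counts):
    """Expand a type -> ownership -> count mapping into registry rows."""
    rows = []
    i = 0
    for ftype, per_owner in counts.items():
        for owner, n in per_owner.items():
            for _ in range(n):
                rows.append([f"f{i}", "X", ftype, owner, "D01", 0.0, 0.0])
                i += 1
    return _registry(rows)


VOLTA_2022_COUNTS = {
    "CHPS": {"Government": 344, "FaithBased": 3, "Private": 50},
    "HealthCentre": {"Government": 117, "FaithBased": 0, "Private": 0},
    "Hospital": {"Government": 14, "FaithBased": 5, "Private": 15},
    "MaternityHome": {"Government": 0, "FaithBased": 0, "Private": 11},
}


def test_ownership_table_reproduces_published_composition():
    tab = ownership_type_table(_composition_registry(VOLTA_2022_COUNTS))
    assert tab.grand_total == 559
    assert tab.within_type_pct.loc["CHPS", "Government"] == pytest.approx(86.6, abs=0.05)
    assert tab.ownership_share_pct["Government"] == pytest.approx(85.0, abs=0.05)
    assert tab.ownership_share_pct["Private"] == pytest.approx(13.6, abs=0.05)
    assert tab.ownership_share_pct["FaithBased"] == pytest.approx(1.4, abs=0.05)
    assert tab.type_share_pct["CHPS"] == pytest.approx(71.0, abs=0.05)
    assert tab.within_ownership_pct.loc["CHPS", "Private"] == pytest.approx(65.8, abs=0.05)
    assert tab.within_ownership_pct.loc["HealthCentre", "Government"] == pytest.approx(24.6, abs=0.05)


def test_one_facility_marginals_are_all_100():
    tab = ownership_type_table(_registry([["f1", "A", "CHPS", "Government", "D01", 0, 0]]))
    assert tab.within_type_pct.loc["CHPS", "Government"] == pytest.approx(100.0)
    assert tab.ownership_share_pct["Government"] == pytest.approx(100.0)
    assert tab.type_share_pct["CHPS"] == pytest.approx(100.0)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------

def test_balanced_2x2_p_is_one():
    assert fisher_exact([[10, 10], [10, 10]]).p_value == pytest.approx(1.0, abs=1e-12)


def test_2x2_example_matches_enumeration_and_scipy():
    import scipy.stats as ss

    table = [[1, 9], [11, 3]]
    res = fisher_exact(table)
    assert res.method == "exact_enumeration"
    assert res.p_value == pytest.approx(fisher_oracle(table), abs=1e-12)
    assert res.p_value == pytest.approx(ss.fisher_exact(table)[1], abs=1e-9)
    assert res.p_value == pytest.approx(0.00276, abs=5e-6)


def test_degenerate_zero_row_raises():
    with pytest.raises(DegenerateTableError):
        fisher_exact([[1, 2, 3], [0, 0, 0]])


def test_exact_mode_matches_oracle_on_random_small_tables(rng):
    for _ in range(60):
        shape = rng.choice([(2, 2), (2, 3), (3, 3)])
        t = rng.integers(0, 7, size=tuple(shape))
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            continue
        res = fisher_exact(t)
        assert res.method == "exact_enumeration"
        assert res.p_value == pytest.approx(fisher_oracle(t), abs=1e-12)


def test_monte_carlo_agrees_with_exact_on_mid_size_table():
    table = [[12, 5, 3], [4, 10, 6]]
    exact = fisher_exact(table)
    mc = fisher_exact(table, max_tables=1, n_draws=40_000, seed=5)
    assert exact.method == "exact_enumeration"
    assert mc.method == "monte_carlo"
    assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)
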