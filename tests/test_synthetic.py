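import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from hmisaccess.config import ConfigError, RegionConfig, YEARS
from hmisaccess.grid import rasterize_lines, rasterize_polygons
from hmisaccess.synthetic import (
    generate_districts,
    generate_facilities,
    generate_population,
    generate_region,
    generate_roads,
    generate_service_histories,
    generate_terrain,
)
from hmisaccess.traveltime import slope_magnitude


def _cfg(**kw):
    base = dict(n_rows=60, n_cols=60, n_facilities=30, seed=1)
    base.update(kw)
    return RegionConfig(**base)


# ---------------------------------------------------------------------------
# determinism and layer independence
# ---------------------------------------------------------------------------

def test_all_layers_deterministic_under_seed():
    cfg = _cfg(seed=5)
    a, b = generate_region(cfg), generate_region(cfg)
    np.testing.assert_array_equal(a.dem.data, b.dem.data)
    np.testing.assert_array_equal(a.landcover.data, b.landcover.data)
    np.testing.assert_array_equal(a.population.data, b.population.data)
    pd.testing.assert_frame_equal(a.registry, b.registry)
    pd.testing.assert_frame_equal(a.records, b.records)
    for fa, fb in zip(a.roads, b.roads):
        assert fa.geometry.equals_exact(fb.geometry, 0)


def test_roads_independent_of_facility_count():
    roads_none = generate_roads(_cfg(n_facilities=0))
    roads_many = generate_roads(_cfg(n_facilities=200))
    assert len(roads_none) >= 1
    for fa, fb in zip(roads_none, roads_many):
        assert fa.geometry.equals_exact(fb.geometry, 0)


# ---------------------------------------------------------------------------
# terrain and water
# ---------------------------------------------------------------------------

def test_terrain_layers_share_grid_and_legend():
    dem, landcover, water = generate_terrain(_cfg())
    assert dem.same_grid(landcover)
    assert dem.shape == (60, 60)
    assert set(np.unique(landcover.data)) <= {1, 2, 3}
    assert len(water) >= 1


def test_water_disabled_rasterises_to_zero_cells():
    cfg = _cfg(water=False)
    dem, landcover, water = generate_terrain(cfg)
    assert water == []
    burned = rasterize_lines(landcover, [f.geometry for f in water]) if water else np.zeros(dem.shape)
    assert (burned == 0).all()


def test_water_forms_connected_barrier():
    dem, landcover, water = generate_terrain(_cfg())
    river = [f.geometry for f in water if f.geometry.geom_type == "LineString"]
    mask = rasterize_lines(landcover, river) > 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    assert n == 1  # a single connected river barrier
    rows = np.nonzero(mask.any(axis=1))[0]
    assert rows[0] == 0 and rows[-1] == dem.n_rows - 1  # spans north to south


def test_slope_matches_hand_central_differences_on_corner_patch():
    """Slope at an interior cell of the 3x3 corner patch equals the
    hand-computed central-difference magnitude."""
    dem, _, _ = generate_terrain(_cfg(seed=1))
    z = dem.data[:3, :3]
    s = dem.cell_size
    d_dcol = (z[1, 2] - z[1, 0]) / (2 * s)
    d_drow = (z[2, 1] - z[0, 1]) / (2 * s)
    expected = np.hypot(d_drow, d_dcol)
    assert slope_magnitude(dem)[1, 1] == pytest.approx(expected, rel=1e-12)


def test_invalid_dimensions_rejected():
    with pytest.raises(ConfigError):
        RegionConfig(n_rows=5, n_cols=60)


# ---------------------------------------------------------------------------
# roads
# ---------------------------------------------------------------------------

def test_road_network_connected_and_touches_two_edges():
    cfg = _cfg()
    roads = generate_roads(cfg)
    assert all("speed_class" in f.properties for f in roads)
    dem, landcover, _ = generate_terrain(cfg)
    mask = rasterize_lines(landcover, [f.geometry for f in roads]) > 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    assert n == 1
    edges_touched = sum(
        [mask[0].any(), mask[-1].any(), mask[:, 0].any(), mask[:, -1].any()]
    )
    assert edges_touched >= 2


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def test_population_conserved_and_nonnegative():
    cfg = _cfg(total_population=123_456.0)
    pop = generate_population(cfg)
    assert (pop.data >= 0).all()
    assert pop.data.sum() == pytest.approx(123_456.0, rel=1e-3)


def test_population_spatially_clustered_vs_shuffle():
    """Variance of 10x10 block sums exceeds that of a uniform shuffle."""
    cfg = _cfg(seed=3)
    pop = generate_population(cfg).data

    def block_var(a):
        blocks = a.reshape(6, 10, 6, 10).sum(axis=(1, 3))
        return blocks.var()

    shuffled = np.random.default_rng(0).permutation(pop.ravel()).reshape(pop.shape)
    assert block_var(pop) > block_var(shuffled)


# ---------------------------------------------------------------------------
# facilities
# ---------------------------------------------------------------------------

def test_zero_error_rate_publishes_true_coordinates():
    cfg = _cfg(coord_error_rate=0.0)
    registry, truth = generate_facilities(cfg, generate_districts(cfg))
    assert (truth["coord_error"] == "none").all()
    np.testing.assert_allclose(registry["x"], truth["x_true"])
    np.testing.assert_allclose(registry["y"], truth["y_true"])


@pytest.mark.parametrize("rate,seed", [(0.05, 0), (0.10, 7), (0.33, 2)])
def test_corrupted_count_is_rounded_fraction(rate, seed):
    cfg = _cfg(coord_error_rate=rate, seed=seed)
    _, truth = generate_facilities(cfg, generate_districts(cfg))
    n_corrupt = int((truth["coord_error"] != "none").sum())
    assert n_corrupt == int(round(rate * cfg.n_facilities))


def test_true_coordinates_inside_assigned_district():
    from shapely.geometry import Point

    cfg = _cfg(seed=4)
    districts = generate_districts(cfg)
    registry, truth = generate_facilities(cfg, districts)
    geoms = {f.properties["district_id"]: f.geometry for f in districts}
    for rec, t in zip(registry.itertuples(), truth.itertuples()):
        assert geoms[rec.district_id].contains(Point(t.x_true, t.y_true))


def test_type_frequencies_converge_to_mix():
    cfg = _cfg(n_facilities=5000, coord_error_rate=0.0, seed=9)
    registry, _ = generate_facilities(cfg, generate_districts(cfg))
    freqs = registry["type"].value_counts(normalize=True)
    for t, p in cfg.type_mix.items():
        assert abs(freqs.get(t, 0.0) - p) < 0.02


def test_empty_district_set_rejected():
    with pytest.raises(ConfigError):
        generate_facilities(_cfg(), [])


# ---------------------------------------------------------------------------
# service histories
# ---------------------------------------------------------------------------

def _histories_for(archetype, n=40, seed=2):
    cfg = _cfg(
        n_facilities=n,
        seed=seed,
        archetype_mix={archetype: 1.0},
        coord_error_rate=0.0,
    )
    registry, _ = generate_facilities(cfg, generate_districts(cfg))
    records, truth = generate_service_histories(registry, cfg)
    assert (truth["archetype"] == archetype).all()
    return registry, records


def test_no_service_archetype_has_zero_records():
    _, records = _histories_for("no_service")
    assert len(records) == 0


def test_closed_archetype_positive_2016_zero_2022():
    _, records = _histories_for("closed")
    by_year = records.groupby(["facility_id", "year"])["count"].sum().unstack(fill_value=0)
    assert (by_year.get(2016, pd.Series(0, index=by_year.index)) > 0).all()
    assert 2022 not in by_year.columns or (by_year[2022] == 0).all()


def test_counts_positive_where_provided():
    _, records = _histories_for("existing_unchanged")
    assert (records["count"] >= 1).all()


def test_caesarean_only_at_hospitals(small_region):
    merged = small_region.records.merge(small_region.registry, on="facility_id")
    caes = merged[merged["indicator"] == "caesarean"]
    assert (caes["type"] == "Hospital").all()


def test_unknown_archetype_rejected():
    cfg = _cfg(coord_error_rate=0.0)
    registry, _ = generate_facilities(cfg, generate_districts(cfg))
    cfg.archetype_mix = {"bogus": 1.0}
    with pytest.raises(ConfigError):
        generate_service_histories(registry, cfg)


def test_years_within_study_span(small_region):
    assert small_region.records["year"].isin(YEARS).all()
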