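"""Hull volumes, impacted fractions, subsetting, resampling, heatmaps."""

import numpy as np
import pytest

from benthovuln.trait_data import (
    MortalityRecord,
    ValidationError,
    build_functional_entities,
    impacted_fe_ids,
)
from benthovuln.trait_space import TraitSpace, gower_distance, select_dimension
from benthovuln.trait_volume import (
    DriverYearCell,
    assign_region,
    decade_summary,
    driver_year_heatmap,
    heatmap_driver_class,
    hull_volume,
    impacted_fraction,
    resample_volume,
    subset_records,
)

from conftest import make_toy_schema, mc_hull_volume, random_table


def make_space(points: np.ndarray, m_selected=None) -> TraitSpace:
    labels = tuple(f"FE{i:03d}" for i in range(len(points)))
    return TraitSpace(
        labels=labels,
        coordinates=np.asarray(points, dtype=float),
        eigenvalues=np.ones(points.shape[1]),
        m_selected=m_selected or points.shape[1],
    )


def record(species="s0000", year=2015, lon=5.0, drivers=("temperature anomaly",), pct=80):
    return MortalityRecord(
        species=species, phylum="Cnidaria", year=year, longitude=lon, latitude=40.0,
        depth_range="", habitat="", drivers=frozenset(drivers), percent_mortality=pct,
    )


class TestHullVolume:
    def test_unit_square(self):
        v, deg = hull_volume(np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float))
        assert not deg
        assert v == pytest.approx(1.0)

    def test_triangle(self):
        v, deg = hull_volume(np.array([[0, 0], [1, 0], [0, 1]], dtype=float))
        assert not deg
        assert v == pytest.approx(0.5)

    def test_too_few_points_degenerate(self):
        v, deg = hull_volume(np.array([[0.0, 0.0], [1.0, 1.0]]))
        assert deg and v == 0.0

    def test_affinely_dependent_points_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        v, deg = hull_volume(pts)
        assert deg and v == 0.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            hull_volume(np.array([[0.0, np.nan], [1, 0], [0, 1]]))

    def test_matches_monte_carlo_oracle_in_4d(self, rng):
        pts = rng.uniform(size=(50, 4))
        v, deg = hull_volume(pts)
        est = mc_hull_volume(pts, 1_000_000, rng)
        assert not deg
        assert v == pytest.approx(est, rel=0.02)

    def test_monotone_under_point_addition(self, rng):
        pts = rng.normal(size=(30, 3))
        v_small, _ = hull_volume(pts[:15])
        v_all, _ = hull_volume(pts)
        assert v_all >= v_small - 1e-12


class TestImpactedFraction:
    def test_all_fes_fraction_one(self, rng):
        space = make_space(rng.uniform(size=(20, 3)))
        res = impacted_fraction(space, [], set(space.labels))
        assert res.fraction == pytest.approx(1.0)
        assert res.n_fes_impacted == 20

    def test_empty_set_fraction_zero(self, rng):
        space = make_space(rng.uniform(size=(20, 3)))
        res = impacted_fraction(space, [], set())
        assert res.fraction == 0.0 and res.degenerate

    def test_interior_subset_strictly_between(self, rng):
        outer = np.array([[0, 0], [4, 0], [0, 4], [4, 4]], dtype=float)
        inner = 1.0 + rng.uniform(size=(5, 2))
        space = make_space(np.vstack([outer, inner]))
        impacted = set(space.labels[4:])
        res = impacted_fraction(space, [], impacted)
        assert 0 < res.fraction < 1

    def test_small_impacted_set_flagged_degenerate(self, rng):
        space = make_space(rng.uniform(size=(20, 4)))
        res = impacted_fraction(space, [], set(space.labels[:3]))  # < m+1 points
        assert res.degenerate and res.fraction == 0.0

    def test_unknown_fe_id_rejected(self, rng):
        space = make_space(rng.uniform(size=(10, 2)))
        with pytest.raises(ValidationError):
            impacted_fraction(space, [], {"FE999"})


class TestSubsetting:
    RECORDS = [record(pct=80), record(pct=90), record(pct=100), record(pct=20), record(pct=50)]

    def test_threshold_filter_uses_geq(self):
        assert len(subset_records(self.RECORDS, min_percent=90)) == 2

    def test_top_bin_is_total_mortality_only(self):
        assert [r.percent_mortality for r in subset_records(self.RECORDS, min_percent=100)] == [100]

    def test_severity_class_filter(self):
        sub = subset_records([record(pct=20), record(pct=50), record(pct=80)], severity="severe")
        assert len(sub) == 1

    def test_empty_region_subset_is_valid(self):
        assert subset_records(self.RECORDS, region="eastern") == []

    def test_contradictory_year_window_errors(self):
        with pytest.raises(ValidationError):
            subset_records(self.RECORDS, year_window=(2020, 1986))

    @pytest.mark.parametrize("lon,region", [(5.0, "western"), (15.0, "central"), (30.0, "eastern")])
    def test_region_banding(self, lon, region):
        assert assign_region(lon) == region


class TestDriverClasses:
    @pytest.mark.parametrize(
        "drivers,expected",
        [
            (("storm",), "storm"),
            (("disease",), "disease"),
            (("storm", "pollution"), "abiotic combination"),
            (("disease", "predator outbreak"), "biotic combination"),
            (("storm", "disease"), "abiotic x biotic"),
        ],
    )
    def test_heatmap_class_assignment(self, drivers, expected):
        assert heatmap_driver_class(record(drivers=drivers)) == expected


@pytest.fixture(scope="module")
def small_world():
    """A 40-species table, its FE space, and a record stream."""
    rng = np.random.default_rng(77)
    schema = make_toy_schema()
    table = random_table(schema, 40, rng)
    fes = build_functional_entities(table)
    space = select_dimension(gower_distance(table, level="fe"), candidates=range(2, 6))
    species = table.species
    records = [
        record(
            species=species[int(rng.integers(len(species)))],
            year=int(rng.integers(1986, 2021)),
            lon=float(rng.uniform(-5, 35)),
            pct=int(rng.integers(1, 11)) * 10,
        )
        for _ in range(300)
    ]
    return table, fes, space, records


class TestResampling:
    def test_full_group_draw_is_deterministic(self, small_world):
        _, fes, space, records = small_world
        group = records[:120]
        summ = resample_volume(group, space, fes, n=len(group), repetitions=20, seed=5)
        assert summ.sd_fraction == 0.0
        full = impacted_fraction(space, fes, impacted_fe_ids(group, fes))
        assert summ.fractions[0] == pytest.approx(full.fraction)
        assert np.all(summ.fractions == summ.fractions[0])

    def test_fixed_seed_reproducible(self, small_world):
        _, fes, space, records = small_world
        a = resample_volume(records, space, fes, n=50, repetitions=30, seed=11)
        b = resample_volume(records, space, fes, n=50, repetitions=30, seed=11)
        assert np.array_equal(a.fractions, b.fractions)
        assert np.array_equal(a.fe_counts, b.fe_counts)

    def test_group_smaller_than_n_errors(self, small_world):
        _, fes, space, records = small_world
        with pytest.raises(ValidationError):
            resample_volume(records[:10], space, fes, n=100, repetitions=5, seed=1)

    def test_summary_recomputable_from_repetitions(self, small_world):
        _, fes, space, records = small_world
        summ = resample_volume(records, space, fes, n=40, repetitions=50, seed=2)
        assert summ.mean_fraction == pytest.approx(np.mean(summ.fractions))
        assert summ.sd_fraction == pytest.approx(np.std(summ.fractions, ddof=1))


class TestHeatmap:
    def test_single_record_yields_one_active_cell(self, small_world):
        _, fes, space, _ = small_world
        recs = [record(year=2000, drivers=("disease",))]
        cells = driver_year_heatmap(recs, space, fes, years=[1999, 2000, 2001])
        active = [c for c in cells if c.n_fes_impacted > 0]
        assert len(active) == 1
        assert (active[0].driver_class, active[0].year) == ("disease", 2000)
        assert len(cells) == 12 * 3

    def test_empty_years_zero_fraction(self, small_world):
        _, fes, space, _ = small_world
        cells = driver_year_heatmap([record(year=2000)], space, fes, years=[1990])
        assert all(c.fraction == 0.0 for c in cells)

    def test_full_grid_has_420_cells(self, small_world):
        _, fes, space, records = small_world
        cells = driver_year_heatmap(records, space, fes, years=range(1986, 2021))
        assert len(cells) == 12 * 35


class TestDecadeSummary:
    def _cells(self, fractions_by_year):
        return [DriverYearCell("all drivers", y, f, n) for y, (f, n) in fractions_by_year.items()]

    def test_constant_fraction_mean_unchanged(self):
        cells = self._cells({y: (0.1, 3) for y in range(1986, 1996)})
        out = decade_summary(cells, window=10)
        assert out["1986-1995"]["mean_fraction"] == pytest.approx(0.1)

    def test_single_active_year_dilutes_by_window(self):
        by_year = {y: (0.0, 0) for y in range(1986, 1996)}
        by_year[1990] = (0.5, 4)
        out = decade_summary(self._cells(by_year), window=10)
        assert out["1986-1995"]["mean_fraction"] == pytest.approx(0.05)

    def test_late_concentration_sharpens_five_year_mean(self):
        by_year = {y: (0.0, 0) for y in range(1986, 1996)}
        for y in range(1991, 1996):
            by_year[y] = (0.4, 5)
        cells = self._cells(by_year)
        dec = decade_summary(cells, window=10)["1986-1995"]["mean_fraction"]
        five = decade_summary(cells, window=5)["1991-1995"]["mean_fraction"]
        assert five == pytest.approx(0.4)
        assert five > dec

    def test_empty_cells_error(self):
        with pytest.raises(ValidationError):
            decade_summary([], window=10)
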