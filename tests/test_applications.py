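"""Site assessment, polyculture ranking, and density profiles."""

import numpy as np
import pandas as pd
import pytest

from aquaniche.applications import (
    SiteQuery,
    assess_site,
    density_profiles,
    overlay_report,
    rank_combinations,
    render_profiles,
)
from aquaniche.environment import VARIABLE_IDS, EnvMatrix
from aquaniche.grid import GridSpec, grid_presences
from aquaniche.model import NicheSuitabilityModel
from aquaniche.synthetic import (
    NicheSpec,
    cell_environments,
    make_occurrences,
    make_rasters,
    two_species_fixture,
)


@pytest.fixture(scope="module")
def fixture():
    return two_species_fixture(seed=1, n_records=250)


@pytest.fixture(scope="module")
def results(fixture):
    return NicheSuitabilityModel(fixture.matrices, seed=1).fit()


def env_values(matrix, i):
    row = matrix.data.iloc[i]
    return {vid: float(row[vid]) for vid in VARIABLE_IDS}


class TestAssessSite:
    def test_location_mode_inside_overlap(self, fixture, results):
        report = assess_site(
            SiteQuery.at_point(*fixture.inside_site), results,
            layers=fixture.layers, grid=fixture.grid,
        )
        assert report.cell is not None
        assert all(report.species_verdicts.values())
        assert report.intersection_verdict is True

    def test_location_mode_outside_both(self, fixture, results):
        report = assess_site(
            SiteQuery.at_point(*fixture.outside_site), results,
            layers=fixture.layers, grid=fixture.grid,
        )
        assert not any(report.species_verdicts.values())
        assert report.intersection_verdict is False

    def test_area_query_resolves_centroid_cell(self, fixture, results):
        lon, lat = fixture.inside_site
        report = assess_site(
            SiteQuery.in_area((lat - 0.2, lat + 0.2), (lon - 0.2, lon + 0.2)),
            results, layers=fixture.layers, grid=fixture.grid,
        )
        assert report.cell == (lon, lat)

    def test_direct_mode_training_vector_included(self, fixture, results):
        m = fixture.matrices[0]
        report = assess_site(SiteQuery.from_values(env_values(m, len(m) // 2)), results)
        assert report.species_verdicts[m.species] is True

    def test_direct_mode_far_vector_excluded(self, fixture, results):
        values = {vid: 1e6 for vid in VARIABLE_IDS}
        report = assess_site(SiteQuery.from_values(values), results)
        assert not any(report.species_verdicts.values())
        assert report.intersection_verdict is False

    def test_direct_mode_missing_variable_named(self, results):
        values = {vid: 1.0 for vid in VARIABLE_IDS[:-1]}
        with pytest.raises(ValueError, match=VARIABLE_IDS[-1]):
            assess_site(SiteQuery.from_values(values), results)

    def test_intersection_verdict_is_and_of_members(self, fixture, results):
        rng = np.random.default_rng(17)
        hvs = results.hypervolumes
        for _ in range(50):
            lon = rng.uniform(0.5, 19.5)
            lat = rng.uniform(0.5, 14.5)
            report = assess_site(
                SiteQuery.at_point(lon, lat), results,
                layers=fixture.layers, grid=fixture.grid,
            )
            assert report.intersection_verdict == all(report.species_verdicts.values())
            for sp, verdict in report.species_verdicts.items():
                assert verdict == hvs[sp].includes(report.projection)

    def test_report_serializes(self, fixture, results):
        report = assess_site(
            SiteQuery.at_point(*fixture.inside_site), results,
            layers=fixture.layers, grid=fixture.grid,
        )
        frame = report.to_frame()
        assert set(frame["species"]) == set(results.species) | {"<intersection>"}
        assert "intersection" in report.to_json()


def three_species_matrices(seed=0, n=200):
    """A and B overlap in a temperature band; C is disjoint from both."""
    grid = GridSpec(30, 0.0, 15.0, 0.0, 30.0)
    layers, mask = make_rasters(
        grid, pixel_arcmin=10, seed=seed,
        field_specs={
            "annual_mean_temp": ("gradient_lon", 10.0, 100.0),
            "annual_precipitation": ("gradient_lon", 30.0, 400.0),
            "elevation_avg": ("gradient_lat", 50.0, 0.0),
        },
    )
    env = cell_environments(layers, grid, mask)
    from aquaniche.environment import build_env_matrix
    from aquaniche.niche import derive_seed

    specs = [
        NicheSpec("A", "box", {"annual_mean_temp": (110.0, 190.0)}),   # lon 1..9
        NicheSpec("B", "box", {"annual_mean_temp": (160.0, 240.0)}),   # lon 6..14
        NicheSpec("C", "box", {"annual_mean_temp": (310.0, 390.0)}),   # lon 21..29
    ]
    mats = []
    for spec in specs:
        recs = make_occurrences(
            spec, layers, grid, n=n, seed=derive_seed(seed, "occ", spec.species), cell_env=env
        )
        mats.append(build_env_matrix(grid_presences(recs, grid), layers, grid))
    return mats


@pytest.fixture(scope="module")
def matrices():
    return three_species_matrices(seed=2)


class TestRankCombinations:

    def test_subset_enumeration_counts(self, matrices):
        ranking = rank_combinations(matrices, sizes={2, 3}, seed=2, n_mc_samples=4000)
        assert len(ranking.table) == 4  # C(3,2) + C(3,3)

    def test_disjoint_species_yield_null_rows(self, matrices):
        ranking = rank_combinations(matrices, sizes={2, 3}, seed=2, n_mc_samples=4000)
        table = ranking.table
        by_combo = {frozenset(t): v for t, v in zip(table["species"], table["volume"])}
        assert by_combo[frozenset({"A", "B"})] > 0
        assert by_combo[frozenset({"A", "C"})] == 0.0
        assert by_combo[frozenset({"B", "C"})] == 0.0
        assert by_combo[frozenset({"A", "B", "C"})] == 0.0
        # feasible pair ranks first
        assert set(table.iloc[0]["species"]) == {"A", "B"}
        assert (table["volume"].diff().dropna() <= 1e-12).all()

    def test_identical_clouds_rank_first(self, matrices):
        twin = EnvMatrix(species="A2", data=matrices[0].data.copy())
        ranking = rank_combinations(matrices + [twin], sizes={2}, seed=3, n_mc_samples=4000)
        assert set(ranking.table.iloc[0]["species"]) == {"A", "A2"}

    def test_sparse_species_skipped_with_reason(self, matrices):
        tiny = EnvMatrix(species="T", data=matrices[0].data.iloc[:2].copy())
        ranking = rank_combinations(matrices + [tiny], sizes={2}, seed=4, n_mc_samples=2000)
        skipped_sets = {frozenset(c) for c, _ in ranking.skipped}
        assert all("T" in s for s in skipped_sets)
        assert len(skipped_sets) == 3
        assert all(reason for _, reason in ranking.skipped)

    def test_needs_two_species(self, matrices):
        from aquaniche.exceptions import DataError

        with pytest.raises(DataError):
            rank_combinations(matrices[:1])


class TestDensityProfiles:
    def test_mode_recovers_gaussian_centre(self):
        rng = np.random.default_rng(5)
        data = pd.DataFrame(
            np.zeros((5000, len(VARIABLE_IDS))), columns=VARIABLE_IDS
        )
        data["soil_ph"] = rng.normal(20.0, 2.0, size=5000)
        data.insert(0, "lat_centre", 0.0)
        data.insert(0, "lon_centre", 0.0)
        m = EnvMatrix(species="sp", data=data)
        (profile,) = density_profiles([m], variables=["soil_ph"])
        assert profile.modes["sp"] == pytest.approx(20.0, abs=0.5)
        assert not profile.degenerate["sp"]

    def test_curves_integrate_to_one(self, fixture):
        profiles = density_profiles(fixture.matrices, variables=["annual_mean_temp", "elevation_avg"])
        for prof in profiles:
            for dens in prof.curves.values():
                integral = np.trapezoid(dens, prof.grid)
                assert 0.98 <= integral <= 1.02

    def test_disjoint_supports_do_not_overlap(self):
        def matrix(name, centre):
            rng = np.random.default_rng(hash(name) % 2**31)
            data = pd.DataFrame(np.zeros((500, len(VARIABLE_IDS))), columns=VARIABLE_IDS)
            data["soil_ph"] = rng.normal(centre, 1.0, size=500)
            data.insert(0, "lat_centre", 0.0)
            data.insert(0, "lon_centre", 0.0)
            return EnvMatrix(species=name, data=data)

        (profile,) = density_profiles([matrix("a", 0.0), matrix("b", 100.0)], variables=["soil_ph"])
        both_high = (profile.curves["a"] > 0.01 * profile.curves["a"].max()) & (
            profile.curves["b"] > 0.01 * profile.curves["b"].max()
        )
        assert not both_high.any()

    def test_degenerate_point_mass(self):
        data = pd.DataFrame(np.zeros((10, len(VARIABLE_IDS))), columns=VARIABLE_IDS)
        data["soil_ph"] = 7.7
        data.insert(0, "lat_centre", 0.0)
        data.insert(0, "lon_centre", 0.0)
        (profile,) = density_profiles(
            [EnvMatrix(species="sp", data=data)], variables=["soil_ph"]
        )
        assert profile.degenerate["sp"] and profile.modes["sp"] == 7.7

    def test_mode_lies_on_grid(self, fixture):
        (profile,) = density_profiles(fixture.matrices, variables=["annual_mean_temp"])
        for mode in profile.modes.values():
            assert mode in profile.grid


class TestOverlayReport:
    def test_cardinality_and_site_markers(self, fixture):
        profiles = density_profiles(
            fixture.matrices, variables=["annual_mean_temp", "elevation_avg"]
        )
        no_site = overlay_report(profiles)
        assert set(no_site["species"]) == {m.species for m in fixture.matrices}
        assert no_site.groupby(["species", "variable"]).ngroups == 4

        site_vals = {"annual_mean_temp": 170.0, "elevation_avg": 400.0}
        with_site = overlay_report(profiles, site_values=site_vals)
        markers = with_site[with_site["species"] == "<site>"]
        assert len(markers) == 2
        assert markers["density"].isna().all()

    def test_missing_site_variable_marker_omitted(self, fixture):
        profiles = density_profiles(fixture.matrices, variables=["annual_mean_temp", "soil_ph"])
        out = overlay_report(profiles, site_values={"annual_mean_temp": 170.0})
        markers = out[out["species"] == "<site>"]
        assert list(markers["variable"]) == ["annual_mean_temp"]

    def test_render_writes_image(self, fixture, tmp_path):
        profiles = density_profiles(fixture.matrices, variables=["annual_mean_temp"])
        path = tmp_path / "profiles.png"
        render_profiles(profiles, path, site_values={"annual_mean_temp": 170.0})
        assert path.exists() and path.stat().st_size > 0
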