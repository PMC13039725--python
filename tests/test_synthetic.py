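"""Generators: determinism, spatial structure, turnover realism, recovery hooks."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import betafutures as bf
from betafutures.synthetic import (
    DEFAULT_LANDUSE_CLASSES,
    default_niches,
    stationary_distribution,
)


class TestLandscape:
    def test_same_seed_is_bit_identical(self, landscape):
        again = bf.generate_landscape(bf.LandscapeSpec(grid_dims=(20, 20), seed=11))
        for v in landscape.variables:
            assert np.array_equal(landscape.data[v], again.data[v], equal_nan=True)

    def test_zero_missing_fraction_leaves_soil_complete(self):
        env = bf.generate_landscape(
            bf.LandscapeSpec(grid_dims=(10, 10), missing_fraction=0.0, seed=1)
        )
        assert not np.isnan(env.data["soil_ph"]).any()

    def test_fields_are_spatially_autocorrelated(self, landscape):
        # lag-1 neighbour correlation (Moran-style) positive for every variable
        for v in landscape.variables:
            arr = landscape.data[v]
            a, b = arr[:, :-1].ravel(), arr[:, 1:].ravel()
            ok = np.isfinite(a) & np.isfinite(b)
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            assert r > 0, f"{v} lacks positive spatial autocorrelation (r={r:.3f})"

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            bf.LandscapeSpec(grid_dims=(0, 5))


class TestDerivedClimate:
    def test_constant_precip_has_zero_seasonality(self):
        out = bf.derive_climate_variables(
            np.zeros(12), np.full(12, 10.0), np.full(12, 50.0)
        )
        assert out["precip_seasonality"] == pytest.approx(0.0)
        assert out["precip_annual"] == pytest.approx(600.0)

    def test_constant_diurnal_range(self):
        tmin = np.linspace(0, 11, 12)
        out = bf.derive_climate_variables(tmin, tmin + 8.0, np.ones(12))
        assert out["diurnal_range_max"] == pytest.approx(8.0)

    def test_single_wet_month_cv_matches_direct_formula(self):
        precip = np.zeros(12)
        precip[0] = 100.0
        # independent brute-force evaluation of 100 * population sd / mean
        mean = precip.sum() / 12
        sd = np.sqrt(np.sum((precip - mean) ** 2) / 12)
        expected = 100.0 * sd / mean
        out = bf.derive_climate_variables(np.zeros(12), np.ones(12), precip)
        assert out["precip_seasonality"] == pytest.approx(expected)

    def test_zero_precipitation_flagged_missing(self):
        out = bf.derive_climate_variables(np.zeros(12), np.ones(12), np.zeros(12))
        assert np.isnan(out["precip_seasonality"])


class TestCommunities:
    def test_perfect_detection_observes_truth(self, filled_landscape):
        niches = default_niches(filled_landscape, n_species=15, seed=3,
                                detection_prob=1.0)
        table = bf.generate_communities(filled_landscape, niches, n_years=1, seed=3)
        for site in table.sites[:20]:
            observed = table.assemblage(int(site))
            truth = set(table.true_presence.columns[table.true_presence.loc[site]])
            assert observed == truth

    def test_identical_environments_identical_true_assemblages(self, filled_landscape):
        env = filled_landscape.copy()
        # force two cells to share an environment exactly
        for v in env.variables:
            flat = env.data[v].ravel()
            flat[1] = flat[0]
        niches = default_niches(env, n_species=30, seed=5)
        table = bf.generate_communities(env, niches, n_years=2, seed=5)
        assert (
            table.true_presence.iloc[0].tolist() == table.true_presence.iloc[1].tolist()
        )

    def test_turnover_increases_with_environmental_distance(self, filled_landscape,
                                                            communities):
        rng = np.random.default_rng(0)
        sites = communities.sites
        z = {}
        for v in filled_landscape.variables:
            col = filled_landscape.data[v].ravel()[sites]
            z[v] = (col - col.mean()) / max(col.std(), 1e-9)
        zmat = np.column_stack(list(z.values()))
        truth = communities.true_presence.to_numpy(bool)
        dists, jacs = [], []
        for _ in range(800):
            i, j = rng.choice(len(sites), 2, replace=False)
            a, b = truth[i], truth[j]
            union = np.sum(a | b)
            if union == 0:
                continue
            jacs.append(1 - np.sum(a & b) / union)
            dists.append(np.linalg.norm(zmat[i] - zmat[j]))
        rho, _ = spearmanr(dists, jacs)
        assert rho > 0, f"turnover does not increase with separation (rho={rho:.2f})"


class TestFutureClimate:
    def test_zero_severity_is_identity(self, filled_landscape):
        scn = bf.ScenarioSpec(name="null", climate_shift_severity={})
        fut = bf.generate_future_climate(filled_landscape, scn, (2060, 2080))
        for v in filled_landscape.variables:
            assert np.array_equal(fut.data[v], filled_landscape.data[v], equal_nan=True)

    def test_linear_shift_construction(self, filled_landscape):
        scn = bf.ScenarioSpec(
            name="s", climate_shift_severity={"tmin_annual": 0.5},
            years=tuple(range(2015, 2081, 5)),
            time_slices=((2040, 2060),),
        )
        fut = bf.generate_future_climate(filled_landscape, scn, (2040, 2060))
        decades = (2050 - 2015) / 10
        np.testing.assert_allclose(
            fut.data["tmin_annual"], filled_landscape.data["tmin_annual"] + 0.5 * decades
        )
        # statics untouched
        np.testing.assert_array_equal(fut.data["twi"], filled_landscape.data["twi"])

    def test_later_slice_shifts_more(self, filled_landscape):
        scn = bf.ScenarioSpec(name="s", climate_shift_severity={"tmax_annual": 0.4})
        early = bf.generate_future_climate(filled_landscape, scn, (2020, 2040))
        late = bf.generate_future_climate(filled_landscape, scn, (2060, 2080))
        d_early = np.nanmean(early.data["tmax_annual"] - filled_landscape.data["tmax_annual"])
        d_late = np.nanmean(late.data["tmax_annual"] - filled_landscape.data["tmax_annual"])
        assert d_late > d_early > 0

    def test_slice_outside_years_rejected(self, filled_landscape):
        scn = bf.ScenarioSpec(name="s", climate_shift_severity={})
        with pytest.raises(ValueError):
            bf.generate_future_climate(filled_landscape, scn, (2090, 2110))


class TestLanduse:
    def test_identity_matrix_freezes_maps(self):
        scn = bf.ScenarioSpec(
            name="s", landuse_transition_matrix=np.eye(len(DEFAULT_LANDUSE_CLASSES))
        )
        maps = bf.generate_landuse(scn, DEFAULT_LANDUSE_CLASSES, seed=2, shape=(8, 8))
        first = maps[min(maps)]
        for m in maps.values():
            np.testing.assert_array_equal(m, first)

    def test_absorbing_urban_never_shrinks(self):
        k = len(DEFAULT_LANDUSE_CLASSES)
        P = np.full((k, k), 0.02) + np.eye(k) * (1 - 0.02 * k)
        urban = DEFAULT_LANDUSE_CLASSES.index("urban")
        P[urban] = 0.0
        P[urban, urban] = 1.0
        scn = bf.ScenarioSpec(name="s", landuse_transition_matrix=P)
        maps = bf.generate_landuse(scn, DEFAULT_LANDUSE_CLASSES, seed=4, shape=(15, 15))
        counts = [int((maps[y] == urban).sum()) for y in sorted(maps)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_long_run_frequencies_approach_stationary(self):
        classes = ("a", "b", "c")
        P = np.array([[0.8, 0.15, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        scn = bf.ScenarioSpec(
            name="s", landuse_transition_matrix=P, classes=classes,
            years=tuple(range(2015, 2516)), time_slices=((2020, 2040),),
        )
        maps = bf.generate_landuse(scn, classes, seed=9, shape=(40, 40))
        final = maps[max(maps)]
        freq = np.bincount(final.ravel(), minlength=3) / final.size
        pi = stationary_distribution(P)
        assert np.abs(freq - pi).max() < 0.05

    def test_malformed_matrix_rejected(self):
        with pytest.raises(ValueError):
            bf.ScenarioSpec(
                name="s",
                landuse_transition_matrix=np.ones((2, 2)),
                classes=("a", "b"),
            )


class TestRuggednessAndIdw:
    def test_flat_grid_is_zero(self):
        np.testing.assert_array_equal(
            bf.ruggedness_index(np.full((5, 5), 7.0)), np.zeros((5, 5))
        )

    def test_centre_cell_hand_example(self):
        grid = np.full((3, 3), 3.0)
        grid[1, 1] = 5.0
        assert bf.ruggedness_index(grid)[1, 1] == pytest.approx(2.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        grid = rng.normal(size=(6, 6))
        np.testing.assert_allclose(
            bf.ruggedness_index(grid), bf.ruggedness_index(grid + 42.0), atol=1e-12
        )

    def test_idw_symmetric_fill(self):
        grid = np.array([[2.0, np.nan, 4.0]])
        assert bf.idw_fill(grid)[0, 1] == pytest.approx(3.0)

    def test_idw_constant_field(self):
        grid = np.full((4, 4), 5.0)
        grid[2, 2] = np.nan
        assert bf.idw_fill(grid)[2, 2] == pytest.approx(5.0)

    def test_idw_fill_within_neighbour_range(self):
        rng = np.random.default_rng(3)
        grid = rng.uniform(2, 9, size=(10, 10))
        holes = rng.choice(100, size=20, replace=False)
        grid.ravel()[holes] = np.nan
        lo, hi = np.nanmin(grid), np.nanmax(grid)
        filled = bf.idw_fill(grid)
        assert np.all(filled >= lo - 1e-12) and np.all(filled <= hi + 1e-12)

    def test_idw_all_missing_errors(self):
        with pytest.raises(ValueError):
            bf.idw_fill(np.full((3, 3), np.nan))


class TestPredictsLike:
    def test_reference_self_similarity_is_one(self, predicts_data):
        from betafutures.habitat import bc_balanced_dissimilarity

        sites = predicts_data.sites
        ab = predicts_data.abundances
        ref = sites[sites.land_use == "reference"].iloc[0]
        vec = (
            ab[(ab.study == ref.study) & (ab.site == ref.site)]
            .set_index("species")["abundance"]
        )
        x = vec.to_numpy(float)
        assert 1.0 - bc_balanced_dissimilarity(x, x) == pytest.approx(1.0)

    def test_no_degradation_truth_gives_unit_bii(self):
        data = bf.generate_predicts_like(
            n_studies=8, seed=2,
            class_factors={c: (1.0, 1.0) for c in DEFAULT_LANDUSE_CLASSES},
        )
        table = bf.estimate_bii_coefficients(data.sites, data.abundances)
        for c in DEFAULT_LANDUSE_CLASSES:
            assert table.static[c] == pytest.approx(1.0, abs=0.1)

    def test_truth_table_exposes_all_classes(self, predicts_data):
        assert set(predicts_data.truth.land_use) == set(DEFAULT_LANDUSE_CLASSES)
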