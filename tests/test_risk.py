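"""IRI computation, HDI classes, exposure tables, scenario differences."""

import numpy as np
import pandas as pd
import pytest

from heatrisk.gridio import GridSpec
from heatrisk.risk import (
    HDIClass,
    class_mask,
    classify_hdi,
    ensemble_summary,
    exposure_distribution,
    iri_nonnormalized,
    iri_normalized,
    people_per_cell,
    scenario_difference,
)


class TestIRINormalized:
    def test_zero_factor_zero_index(self):
        assert iri_normalized(0.0, 0.7, 0.9) == 0.0
        assert iri_normalized(0.5, 0.0, 0.9) == 0.0

    def test_unit_factors_give_hundred(self):
        assert iri_normalized(1.0, 1.0, 1.0) == 100.0

    def test_present_hazard_bounds_index(self):
        # hazard 0.002 caps IRI at 0.2% whatever exposure/vulnerability are
        assert iri_normalized(0.002, 0.9, 0.99) <= 0.2
        assert iri_normalized(0.002, 1.0, 1.0) == pytest.approx(0.2)

    def test_out_of_range_factor_rejected(self):
        with pytest.raises(ValueError):
            iri_normalized(1.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            iri_normalized(0.5, -0.1, 0.5)

    def test_nan_propagates(self):
        out = iri_normalized(np.array([0.5, np.nan]), np.array([1.0, 1.0]), 0.5)
        assert np.isnan(out[1]) and np.isfinite(out[0])


class TestIRINonNormalized:
    def test_zero_population_zero_risk(self):
        assert iri_nonnormalized(0.5, 0.0, 0.4) == 0.0

    def test_linear_in_population(self, rng):
        pop = rng.lognormal(3, 1, size=(4, 4))
        a = iri_nonnormalized(0.1, pop, 0.4)
        b = iri_nonnormalized(0.1, 2 * pop, 0.4)
        assert np.allclose(b, 2 * a)

    def test_matches_elementwise_product(self, rng):
        hazard = rng.uniform(0, 1, size=(3, 3))
        pop = rng.lognormal(2, 1, size=(3, 3))
        vuln = rng.uniform(0.1, 0.7, size=(3, 3))
        got = iri_nonnormalized(hazard, pop, vuln)
        for i in range(3):
            for j in range(3):
                assert got[i, j] == hazard[i, j] * pop[i, j] * vuln[i, j]

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            iri_nonnormalized(0.5, -1.0, 0.4)


class TestClassifyHDI:
    def test_report_cutoffs_strict(self):
        hdi = np.array([0.54, 0.55, 0.80, 0.81, np.nan])
        classes = classify_hdi(hdi)
        assert classes[0] == HDIClass.LOW
        assert classes[1] == HDIClass.MEDIUM
        assert classes[2] == HDIClass.MEDIUM
        assert classes[3] == HDIClass.VERY_HIGH
        assert classes[4] == HDIClass.NO_DATA

    def test_three_country_world_join(self):
        raster = np.array([[0, 0, 1], [2, 2, 1]])
        hdi_by_country = {0: 0.45, 1: 0.70, 2: 0.90}
        field = np.vectorize(hdi_by_country.get)(raster)
        classes = classify_hdi(field)
        assert np.all(classes[raster == 0] == HDIClass.LOW)
        assert np.all(classes[raster == 1] == HDIClass.MEDIUM)
        assert np.all(classes[raster == 2] == HDIClass.VERY_HIGH)

    def test_masks_partition_cells_with_data(self, rng):
        hdi = rng.uniform(0.3, 0.95, size=(6, 6))
        hdi[0, 0] = np.nan
        classes = classify_hdi(hdi)
        total = sum(
            class_mask(classes, c).sum()
            for c in (HDIClass.LOW, HDIClass.MEDIUM, HDIClass.VERY_HIGH)
        )
        assert total == np.isfinite(hdi).sum()
        assert class_mask(classes, None).sum() == np.isfinite(hdi).sum()


class TestExposure:
    @pytest.fixture()
    def grid(self):
        return GridSpec.regular_global(4, 4)

    def test_single_cell_single_bin(self, grid):
        pop = np.zeros((4, 4))
        pop[1, 2] = 10.0
        field = np.full((4, 4), 0.3)
        people = people_per_cell(pop, grid)
        table = exposure_distribution(
            field, pop, grid, [0.0, 1.0], present_global_people=people.sum()
        )
        assert table["pop_pct"].sum() == pytest.approx(100.0)

    def test_conservation_against_direct_sum(self, grid, rng):
        pop = rng.lognormal(2, 1, size=(4, 4))
        pop[rng.uniform(size=(4, 4)) < 0.3] = 0.0
        field = rng.uniform(0, 1, size=(4, 4))
        present = people_per_cell(pop, grid).sum()
        table = exposure_distribution(field, pop, grid, np.linspace(0, 1, 6), present)
        direct = people_per_cell(pop, grid)[pop > 0].sum() / present * 100
        assert table["pop_pct"].sum() == pytest.approx(direct, rel=1e-12)

    def test_empty_mask_all_zero(self, grid, rng):
        pop = rng.lognormal(2, 1, size=(4, 4))
        field = rng.uniform(0, 1, size=(4, 4))
        table = exposure_distribution(
            field, pop, grid, [0, 0.5, 1.0], 1000.0, mask=np.zeros((4, 4), bool)
        )
        assert (table["pop_pct"] == 0).all()

    def test_overlapping_bins_rejected(self, grid):
        with pytest.raises(ValueError):
            exposure_distribution(
                np.zeros((4, 4)), np.ones((4, 4)), grid, [0.0, 0.5, 0.5, 1.0], 1.0
            )

    def test_uninhabited_cells_excluded(self, grid):
        pop = np.ones((4, 4))
        pop[0] = 0.0
        field = np.zeros((4, 4))
        present = people_per_cell(np.ones((4, 4)), grid).sum()
        table = exposure_distribution(field, pop, grid, [-0.5, 0.5], present)
        expected = people_per_cell(pop, grid)[pop > 0].sum() / present * 100
        assert table["pop_pct"].sum() == pytest.approx(expected)

    def test_area_weighting_uses_cell_area(self, grid):
        # equal density everywhere: polar rows carry less population
        pop = np.ones((4, 4))
        people = people_per_cell(pop, grid)
        assert people[0, 0] < people[1, 0]
        assert people[0, 0] == pytest.approx(people[3, 0])


class TestEnsembleSummary:
    def _table(self, values):
        return pd.DataFrame(
            {"bin_low": [0.0, 0.5], "bin_high": [0.5, 1.0], "pop_pct": values}
        )

    def test_single_model_median_is_itself(self):
        out = ensemble_summary([self._table([1.0, 2.0])])
        assert list(out["pop_pct_median"]) == [1.0, 2.0]
        assert list(out["pop_pct_min"]) == list(out["pop_pct_max"])

    def test_three_model_median_and_range(self):
        out = ensemble_summary(
            [self._table([1.0, 1.0]), self._table([2.0, 2.0]), self._table([10.0, 10.0])]
        )
        assert list(out["pop_pct_median"]) == [2.0, 2.0]
        assert list(out["pop_pct_min"]) == [1.0, 1.0]
        assert list(out["pop_pct_max"]) == [10.0, 10.0]

    def test_even_count_matches_sort_oracle(self, rng):
        vals = rng.uniform(size=(4, 2))
        out = ensemble_summary([self._table(v) for v in vals])
        for b in range(2):
            col = np.sort(vals[:, b])
            assert out["pop_pct_median"][b] == pytest.approx((col[1] + col[2]) / 2)

    def test_mismatched_bins_rejected(self):
        other = pd.DataFrame(
            {"bin_low": [0.0, 0.6], "bin_high": [0.6, 1.0], "pop_pct": [1, 2]}
        )
        with pytest.raises(ValueError):
            ensemble_summary([self._table([1.0, 2.0]), other])


class TestScenarioDifference:
    def test_identical_fields_zero(self, rng):
        a = rng.uniform(size=(3, 3))
        assert np.all(scenario_difference(a, a) == 0)

    def test_antisymmetry(self, rng):
        a = rng.uniform(size=(3, 3))
        b = rng.uniform(size=(3, 3))
        assert np.allclose(scenario_difference(a, b), -scenario_difference(b, a))

    def test_missing_propagates(self):
        a = np.array([1.0, np.nan])
        b = np.array([0.5, 0.5])
        out = scenario_difference(a, b)
        assert out[0] == 0.5 and np.isnan(out[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scenario_difference(np.zeros((2, 2)), np.zeros((3, 3)))
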