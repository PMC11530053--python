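"""Index-property correlation, simple regression and direction allocation."""

import warnings

import numpy as np
import pandas as pd
import pytest

from adrank import (PropertyTable, allocate_property_to_index, correlate,
                    criterion_directions_from_properties, fit_simple_regression,
                    SyntheticPanelSpec, synthetic_qspr_panel)
from adrank.qspr import PROPERTY_DIRECTIONS, PROPERTY_VOCABULARY, qspr_fit_table


def small_panel(seed=0, noise_scale=1.0):
    plant = {p: (idx, s, b, sd * noise_scale)
             for p, (idx, s, b, sd) in SyntheticPanelSpec().plant.items()}
    return synthetic_qspr_panel(SyntheticPanelSpec(seed=seed, plant=plant))


class TestCorrelate:
    def test_property_equal_to_index_has_r_one(self):
        _, idx, _, _ = small_panel()
        props = PropertyTable(pd.DataFrame({"molecular_weight": idx["M1"]},
                                           index=idx.index))
        corr = correlate(idx, props)
        assert corr.loc["M1", "molecular_weight"] == pytest.approx(1.0)

    def test_negated_index_has_r_minus_one(self):
        _, idx, _, _ = small_panel()
        props = PropertyTable(pd.DataFrame({"density": -idx["H"]}, index=idx.index))
        assert correlate(idx, props).loc["H", "density"] == pytest.approx(-1.0)

    def test_planted_linear_relation_gives_high_r(self):
        """property = 2*M1 + small noise -> r > 0.99 (stated seed)."""
        spec = SyntheticPanelSpec(seed=7, plant={"boiling_point": ("M1", 2.0, 150.0, 1.0)})
        _, idx, props, _ = synthetic_qspr_panel(spec)
        assert correlate(idx, props).loc["M1", "boiling_point"] > 0.99

    def test_constant_property_flagged_missing_not_zero(self):
        _, idx, _, _ = small_panel()
        props = PropertyTable(pd.DataFrame({"complexity": np.full(len(idx), 5.0)},
                                           index=idx.index))
        assert np.isnan(correlate(idx, props).loc["M1", "complexity"])

    def test_missing_values_pairwise_deleted(self):
        _, idx, _, _ = small_panel()
        col = idx["M2"].to_numpy().astype(float).copy()
        col[0] = np.nan
        props = PropertyTable(pd.DataFrame({"molecular_weight": col}, index=idx.index))
        corr = correlate(idx, props)
        assert corr.loc["M2", "molecular_weight"] == pytest.approx(1.0)

    def test_affine_rescaling_of_property_preserves_correlations(self):
        _, idx, props, _ = small_panel(seed=3)
        rescaled = PropertyTable(props.df * 1.8 + 32.0)  # unit change
        c1, c2 = correlate(idx, props), correlate(idx, rescaled)
        assert np.allclose(c1.to_numpy(), c2.to_numpy(), equal_nan=True)


class TestFitSimpleRegression:
    def test_exact_line_recovered(self):
        f = fit_simple_regression([0, 1, 2], [0, 2, 4])
        assert (f.slope, f.intercept, f.r_squared) == pytest.approx((2.0, 0.0, 1.0))

    def test_constant_y_gives_zero_slope_zero_r2(self):
        f = fit_simple_regression([1, 2, 3], [5, 5, 5])
        assert (f.slope, f.r_squared) == (0.0, 0.0)

    def test_constant_x_is_singular(self):
        with pytest.raises(ValueError, match="singular"):
            fit_simple_regression([2, 2, 2], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_simple_regression([1, 2], [1, 2])

    def test_r_squared_is_pearson_r_squared(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = 3 * x + rng.normal(size=20)
        f = fit_simple_regression(x, y)
        assert f.r_squared == pytest.approx(f.pearson_r ** 2, abs=1e-9)

    def test_slope_recovery_within_three_se_on_95_percent_of_replicates(self):
        """200 seeded 12-molecule panels: fitted slope within 3 SE of the
        planted slope in at least 95% of replicates."""
        hits = total = 0
        for seed in range(200):
            spec = SyntheticPanelSpec(
                seed=seed, plant={"boiling_point": ("M1", 2.0, 150.0, 8.0)})
            _, idx, props, truth = synthetic_qspr_panel(spec)
            f = fit_simple_regression(idx["M1"], props.df["boiling_point"],
                                      "M1", "boiling_point")
            total += 1
            hits += abs(f.slope - truth["boiling_point"]["slope"]) <= 3 * f.stderr_slope
        assert hits / total >= 0.95


class TestAllocationAndDirections:
    def test_strongest_correlation_wins(self):
        corr = pd.DataFrame({"boiling_point": [0.9], "density": [0.5]}, index=["M1"])
        assert allocate_property_to_index(corr) == {"M1": "boiling_point"}

    def test_tie_breaks_toward_earlier_vocabulary_property(self):
        corr = pd.DataFrame({"boiling_point": [-0.8], "melting_point": [0.8]},
                            index=["M1"])
        # melting_point precedes boiling_point in the vocabulary
        assert allocate_property_to_index(corr) == {"M1": "melting_point"}

    def test_all_missing_leaves_index_unallocated_benefit_default(self):
        corr = pd.DataFrame({"density": [np.nan]}, index=["M1"])
        with pytest.warns(UserWarning, match="unallocated"):
            alloc = allocate_property_to_index(corr)
        assert alloc == {"M1": None}
        with pytest.warns(UserWarning, match="benefit"):
            d = criterion_directions_from_properties(alloc)
        assert d.direction == ["benefit"]

    def test_fixed_property_direction_table(self):
        d = criterion_directions_from_properties({"M1": "density", "M2": "boiling_point"})
        assert dict(zip(d.criteria, d.direction)) == {"M1": "cost", "M2": "benefit"}
        assert set(PROPERTY_DIRECTIONS) == set(PROPERTY_VOCABULARY)

    def test_planted_allocation_recovered_at_small_noise(self):
        """Each property planted on a distinct index at 10x-reduced noise:
        the allocation map inverts the plant exactly."""
        _, idx, props, truth = small_panel(seed=11, noise_scale=0.1)
        alloc = allocate_property_to_index(correlate(idx, props))
        for prop, info in truth.items():
            assert alloc[info["index"]] == prop

    def test_fit_table_covers_all_pairs(self):
        _, idx, props, _ = small_panel(seed=2)
        table = qspr_fit_table(idx, props)
        assert len(table) == 6 * 6
        assert (table["n_used"] >= 3).all()
        assert np.allclose(table["r_squared"], table["pearson_r"] ** 2, atol=1e-9)
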