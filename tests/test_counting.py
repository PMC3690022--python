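"""Counting, densities, bead QC arithmetic and calibration statistics."""

import math

import numpy as np
import pytest

from fibercount import (
    BeadSpec,
    CountingRules,
    DilutionReport,
    beads_per_ml,
    count_fibers,
    dual_mode_counts,
    fiber_concentration,
    fiber_density,
    manual_comparison_report,
    regression_through_origin,
)
from tests.test_shapes import make_particle


class TestCountFibers:
    def test_empty_list(self, default_rules):
        assert count_fibers([], default_rules) == (0, [])

    def test_mixed_fibers_and_debris(self, default_rules):
        fibers = [make_particle(length_um=10 + i) for i in range(5)]
        debris = [make_particle(circularity=0.9, aspect_ratio=1.2) for _ in range(3)]
        n, accepted = count_fibers(fibers + debris, default_rules)
        assert n == 5
        assert accepted == fibers

    def test_boundary_length_excluded(self, default_rules):
        n, _ = count_fibers([make_particle(length_um=4.9)], default_rules)
        assert n == 0


class TestDualModeCounts:
    def _tiles(self, n_refl, n_fluo):
        refl = {(0, 0): [make_particle(length_um=10) for _ in range(n_refl)]}
        fluo = {(0, 0): [make_particle(length_um=10) for _ in range(n_fluo)]}
        return refl, fluo

    def test_fraction(self, default_rules):
        refl, fluo = self._tiles(10, 5)
        sc = dual_mode_counts(refl, fluo, default_rules, tile_area_mm2=0.3185)
        assert sc.total_fibers_reflection == 10
        assert sc.chrysotile_fibers_fluorescence == 5
        assert sc.chrysotile_fraction == pytest.approx(0.5)

    def test_empty_slide_fraction_flagged(self, default_rules):
        refl, fluo = self._tiles(0, 0)
        sc = dual_mode_counts(refl, fluo, default_rules, tile_area_mm2=0.3185)
        assert sc.chrysotile_fraction is None

    def test_grid_mismatch_raises(self, default_rules):
        refl, fluo = self._tiles(1, 1)
        fluo[(0, 1)] = []
        with pytest.raises(ValueError, match="grid"):
            dual_mode_counts(refl, fluo, default_rules, tile_area_mm2=0.3185)


class TestDensityAndConcentration:
    def test_full_scan_density(self):
        # 344 fibers over 108 tiles of 0.3185 mm^2 -> 10.0 f/mm^2
        assert fiber_density(344, 108, 0.3185) == pytest.approx(10.0, abs=0.005)

    def test_single_tile(self):
        assert fiber_density(1, 1, 0.3185) == pytest.approx(1 / 0.3185)

    def test_zero_fibers(self):
        assert fiber_density(0, 10, 0.3185) == 0.0

    def test_zero_tiles_error(self):
        with pytest.raises(ValueError):
            fiber_density(1, 0, 0.3185)

    def test_density_reconstructs_count(self):
        n_tiles, area, count = 108, 0.3185, 344
        d = fiber_density(count, n_tiles, area)
        assert d * n_tiles * area == pytest.approx(count, abs=1e-9)

    def test_concentration_arithmetic(self):
        assert fiber_concentration(10.0, 385.0, 1000.0) == pytest.approx(3.85)
        assert fiber_concentration(0.0, 385.0, 1000.0) == 0.0

    def test_concentration_decreases_with_volume(self):
        assert fiber_concentration(10.0, 385.0, 1e9) < 1e-4
        with pytest.raises(ValueError):
            fiber_concentration(10.0, 385.0, 0.0)


class TestBeadsPerMl:
    def test_scaling_structure(self):
        spec = BeadSpec(1e-9, 1.05, 2.0)
        base = beads_per_ml(spec)
        assert beads_per_ml(BeadSpec(2e-9, 1.05, 2.0)) == pytest.approx(2 * base)
        assert beads_per_ml(BeadSpec(1e-9, 1.05, 4.0)) == pytest.approx(base / 8)

    def test_oracle_concentration_over_bead_mass(self):
        # independent route: number = C / (mass of one bead)
        C, rho, phi = 4.4e-9, 1.05, 2.0
        bead_mass_g = rho * math.pi * phi**3 / 6.0 * 1e-12
        assert beads_per_ml(BeadSpec(C, rho, phi)) == pytest.approx(C / bead_mass_g)
        assert beads_per_ml(BeadSpec(C, rho, phi)) == pytest.approx(1.0e3, rel=0.01)

    def test_unit_inversion(self):
        rho, phi = 1.05, 2.0
        C = rho * math.pi * phi**3 * 1e-12 / 6.0
        assert beads_per_ml(BeadSpec(C, rho, phi)) == pytest.approx(1.0)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            BeadSpec(0.0, 1.05, 2.0)


class TestRegressionThroughOrigin:
    def test_exact_proportionality(self):
        slope, r2 = regression_through_origin([1, 2, 3], [2, 4, 6])
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_hand_computed_case(self):
        slope, _ = regression_through_origin([1, 2], [2, 2])
        assert slope == pytest.approx(1.2)

    def test_zero_response(self):
        slope, _ = regression_through_origin([1, 2, 3], [0, 0, 0])
        assert slope == 0.0

    def test_all_zero_x_error(self):
        with pytest.raises(ValueError):
            regression_through_origin([0, 0], [1, 2])

    def test_least_squares_oracle(self):
        # brute-force 1-D minimization over candidate slopes
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, 20)
        y = 1.7 * x + rng.normal(0, 0.5, 20)
        slope, _ = regression_through_origin(x, y)
        grid = np.linspace(slope - 0.5, slope + 0.5, 4001)
        sse = [((y - s * x) ** 2).sum() for s in grid]
        assert abs(grid[int(np.argmin(sse))] - slope) < 3e-4


class TestDilutionReport:
    def test_level_arithmetic(self):
        rep = DilutionReport.from_replicates(
            [80, 40, 20, 10], [[80, 80, 80], [40, 40, 40], [20, 20, 20], [10, 10, 10]]
        )
        assert rep.slope == pytest.approx(1.0)
        assert rep.r_squared == pytest.approx(1.0)

    def test_mismatched_levels_raise(self):
        with pytest.raises(ValueError):
            DilutionReport.from_replicates([80, 40], [[80]])


class TestManualComparison:
    def test_identical_series_zero_bias(self):
        rep = manual_comparison_report([10, 20, 30], [10, 20, 30])
        assert rep["bias_percent"] == pytest.approx(0.0)

    @pytest.mark.parametrize("factor, bias", [(0.9, -10.0), (1.25, 25.0)])
    def test_proportional_bias(self, factor, bias):
        manual = np.array([12, 25, 40, 80], float)
        rep = manual_comparison_report(factor * manual, manual)
        assert rep["bias_percent"] == pytest.approx(bias)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            manual_comparison_report([1, 2], [1, 2, 3])
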