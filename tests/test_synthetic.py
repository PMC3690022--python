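"""Synthetic slide generator: ground truth, selectivity, determinism."""

import numpy as np
import pytest
from skimage.measure import label as sk_label

from fibercount import (
    SceneParams,
    TileGeometry,
    generate_bead_field,
    generate_dilution_series,
    generate_slide,
)


def components_above(pixels, level, min_px=4):
    lab = sk_label(pixels.astype(float) > level, connectivity=2)
    return sum(1 for v in np.bincount(lab.ravel())[1:] if v >= min_px)


class TestGenerateSlide:
    def test_empty_scene(self, small_geometry):
        s = generate_slide(SceneParams(n_chrysotile=0, noise_sigma=0.0, seed=1), geometry=small_geometry)
        assert s.registry == []
        # nothing but the (noise-free) background gradient remains
        base, grad, _ = SceneParams().background
        assert s.reflection[0].pixels.min() >= base
        assert np.ptp(s.reflection[0].pixels.astype(float)) <= 1.5 * grad

    def test_fluorescence_components_match_chrysotile(self, full_geometry):
        scene = SceneParams(n_chrysotile=10, noise_sigma=0.0, seed=4)
        s = generate_slide(scene, geometry=full_geometry)
        fl = s.fluorescence[0].pixels.astype(float)
        base = SceneParams().fluorescence_background[0]
        assert components_above(fl, base + 2000) == 10

    def test_mixed_scene_visibility_counts(self, full_geometry):
        scene = SceneParams(n_chrysotile=5, n_amosite=5, noise_sigma=0.0, seed=9)
        s = generate_slide(scene, geometry=full_geometry)
        assert s.visible_count("reflection") == 10
        assert s.visible_count("fluorescence") == 5
        refl = s.reflection[0].pixels.astype(float)
        assert components_above(refl, SceneParams().background[0] + SceneParams().background[1] + 2000) == 10

    def test_selectivity_no_foreign_signal_in_fluorescence(self, full_geometry):
        """Amosite, debris and bubbles leave the fluorescence canvas untouched."""
        kwargs = dict(n_chrysotile=0, n_amosite=6, n_debris=4, n_bubbles=2, noise_sigma=0.0)
        s = generate_slide(SceneParams(seed=21, **kwargs), geometry=full_geometry)
        blank = generate_slide(
            SceneParams(seed=21, n_chrysotile=0, noise_sigma=0.0), geometry=full_geometry
        )
        # the fluorescence canvas is the bare background, bit-identical to a
        # scene containing nothing at all
        assert (s.fluorescence[0].pixels == blank.fluorescence[0].pixels).all()

    def test_registry_counts_by_class(self, small_geometry):
        scene = SceneParams(n_chrysotile=3, n_debris=2, noise_sigma=0.0, seed=2)
        s = generate_slide(scene, geometry=small_geometry)
        assert s.class_count("chrysotile") == 3
        assert s.class_count("debris") == 2
        assert len(s.registry) == 5

    def test_bit_identical_regeneration(self, small_geometry):
        scene = SceneParams(n_chrysotile=4, seed=33)
        a = generate_slide(scene, geometry=small_geometry)
        b = generate_slide(scene, geometry=small_geometry)
        assert (a.reflection[0].pixels == b.reflection[0].pixels).all()
        assert (a.fluorescence[0].pixels == b.fluorescence[0].pixels).all()
        assert a.registry == b.registry

    def test_objects_land_in_registered_tile(self, small_geometry):
        scene = SceneParams(n_chrysotile=6, seed=12)
        s = generate_slide(scene, grid=(2, 2), geometry=small_geometry)
        th, tw = small_geometry.shape
        ps = small_geometry.pixel_size
        for r in s.registry:
            row = int(r.center_y_um / (th * ps))
            col = int(r.center_x_um / (tw * ps))
            assert (row, col) == (r.tile_row, r.tile_col)

    def test_infeasible_placement_raises(self, small_geometry):
        with pytest.raises(RuntimeError, match="crowded"):
            generate_slide(SceneParams(n_chrysotile=2000, seed=0), geometry=small_geometry)

    def test_debris_aspect_bounds_validated(self):
        with pytest.raises(ValueError):
            SceneParams(debris_aspect=(1.0, 3.5))
        with pytest.raises(ValueError):
            SceneParams(n_chrysotile=-1)


class TestDilutionSeries:
    def test_structure_and_expected_means(self, small_geometry):
        base = SceneParams(n_chrysotile=16, noise_sigma=0.0)
        levels = generate_dilution_series(
            base, [1.0, 0.5, 0.25, 0.125], 3, master_seed=5, geometry=small_geometry
        )
        assert [lv.expected_mean for lv in levels] == [16, 8, 4, 2]
        assert sum(len(lv.slides) for lv in levels) == 12

    def test_deterministic_regeneration(self, small_geometry):
        base = SceneParams(n_chrysotile=10)
        a = generate_dilution_series(base, [1.0, 0.5], 2, master_seed=3, geometry=small_geometry)
        b = generate_dilution_series(base, [1.0, 0.5], 2, master_seed=3, geometry=small_geometry)
        for la, lb in zip(a, b):
            for sa, sb in zip(la.slides, lb.slides):
                assert (sa.reflection[0].pixels == sb.reflection[0].pixels).all()

    def test_counts_poisson_scaled(self, small_geometry):
        base = SceneParams(n_chrysotile=12)
        levels = generate_dilution_series(base, [1.0, 0.25], 4, master_seed=1, geometry=small_geometry)
        lo = [s.class_count("chrysotile") for s in levels[1].slides]
        hi = [s.class_count("chrysotile") for s in levels[0].slides]
        assert np.mean(lo) < np.mean(hi)

    def test_ascending_factors_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            generate_dilution_series(SceneParams(), [0.5, 1.0], 1, geometry=small_geometry)


class TestBeadField:
    def test_zero_density_blank(self, small_geometry):
        tiles, count = generate_bead_field(2.0, 0.0, geometry=small_geometry, seed=1)
        assert count == 0

    def test_mean_count_matches_area_arithmetic(self):
        # 100 beads/mm^2 on one 650x490 um tile -> mean 31.85
        geom = TileGeometry()
        counts = [
            generate_bead_field(2.0, 100.0, geometry=geom, seed=s)[1] for s in range(40)
        ]
        assert np.mean(counts) == pytest.approx(31.85, rel=0.15)

    def test_seed_reproducibility(self, small_geometry):
        a_tiles, a_n = generate_bead_field(2.0, 50.0, geometry=small_geometry, seed=9)
        b_tiles, b_n = generate_bead_field(2.0, 50.0, geometry=small_geometry, seed=9)
        assert a_n == b_n
        assert (a_tiles[0].pixels == b_tiles[0].pixels).all()
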