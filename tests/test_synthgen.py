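"""Synthetic-scene generator: patterns, seeding, rendering, ground truth."""

import numpy as np
import pandas as pd
import pytest

from printarray import (
    GrowthParams, NoiseParams, PrintingMap, make_printing_map,
    render_reference_image, render_scene, sample_initial_cells,
)
from printarray.synthgen import (
    A, B, droplet_volume_ml, one_colony_per_droplet_scene, _render_disks,
)


class TestPrintingMap:
    def test_segregated_halves_splits_longer_axis(self):
        m = make_printing_map(7, 8, "segregated-halves")
        assert m.assignment.shape == (8, 7)
        assert (m.assignment[:4, :] == "A").all()
        assert (m.assignment[4:, :] == "B").all()

    def test_single_mixed_droplet(self):
        m = make_printing_map(1, 1, "mixed", mix_fraction=0.5)
        assert m.assignment[0, 0] == "MIXED"
        assert m.mix_fraction == 0.5

    def test_checkerboard_2x2(self):
        m = make_printing_map(2, 2, "checkerboard")
        assert m.assignment.tolist() == [["A", "B"], ["B", "A"]]

    def test_strips_widths_must_cover_axis(self):
        m = make_printing_map(7, 20, "strips", strip_widths=[13, 7])
        assert (m.assignment[:13] == "A").all()
        assert (m.assignment[13:] == "B").all()
        with pytest.raises(ValueError, match="sum"):
            make_printing_map(7, 8, "strips", strip_widths=[3, 3])

    def test_unknown_pattern_and_bad_custom_grid(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            make_printing_map(2, 2, "spiral")
        with pytest.raises(ValueError, match="shape"):
            make_printing_map(3, 3, "custom", grid=np.full((2, 2), "A"))

    def test_invariant_validation(self):
        with pytest.raises(ValueError):
            PrintingMap(n_x=0, n_y=1, assignment=np.empty((1, 0), object))
        with pytest.raises(ValueError, match="mix_fraction"):
            make_printing_map(1, 1, "mixed", mix_fraction=1.5)

    def test_json_and_csv_round_trip(self, tmp_path, halves_map):
        p = tmp_path / "map.json"
        halves_map.to_json(p)
        back = PrintingMap.from_json(p)
        assert back.assignment.tolist() == halves_map.assignment.tolist()
        assert back.pitch == halves_map.pitch
        c = tmp_path / "map.csv"
        halves_map.to_csv(c)
        back2 = PrintingMap.from_csv(c)
        assert back2.assignment.tolist() == halves_map.assignment.tolist()


class TestReferenceRender:
    def test_all_a_map_contains_only_a_and_background(self):
        m = make_printing_map(3, 3, "custom", grid=np.full((3, 3), "A"))
        ref = render_reference_image(m, 1.515)
        assert set(np.unique(ref.labels)) <= {0, A}
        assert (ref.labels == A).any()

    def test_empty_map_renders_all_background(self):
        m = make_printing_map(2, 2, "custom", grid=np.full((2, 2), "EMPTY"))
        ref = render_reference_image(m, 1.515)
        assert not ref.labels.any()

    def test_unresolvable_pixel_size_rejected(self, halves_map):
        with pytest.raises(ValueError, match="pixel_size"):
            render_reference_image(halves_map, 200.0)

    def test_mixed_render_is_seeded(self, mixed_map):
        a = render_reference_image(mixed_map, 3.0, seed=5)
        b = render_reference_image(mixed_map, 3.0, seed=5)
        c = render_reference_image(mixed_map, 3.0, seed=6)
        assert np.array_equal(a.labels, b.labels)
        assert not np.array_equal(a.labels, c.labels)


class TestInitialCells:
    def test_mean_cells_per_droplet_matches_poisson_mean(self):
        # 500 droplets at 1e8 cells/mL in 110-µm droplets: mean 69.7
        grid = np.full((25, 20), "A")
        m = make_printing_map(20, 25, "custom", grid=grid)
        cells = sample_initial_cells(m, 1e8, seed=11)
        n_droplets = 500
        mean = len(cells) / n_droplets
        expect = 1e8 * droplet_volume_ml(110.0)
        se = np.sqrt(expect / n_droplets)
        assert abs(mean - expect) < 3 * se
        assert expect == pytest.approx(69.7, abs=0.05)

    def test_doubling_density_doubles_the_mean(self):
        grid = np.full((25, 20), "A")
        m = make_printing_map(20, 25, "custom", grid=grid)
        cells = sample_initial_cells(m, 2e8, seed=12)
        expect = 2e8 * droplet_volume_ml(110.0)
        assert expect == pytest.approx(139.4, abs=0.1)
        se = np.sqrt(expect / 500)
        assert abs(len(cells) / 500 - expect) < 3 * se

    def test_zero_density_gives_no_cells(self, halves_map):
        assert len(sample_initial_cells(halves_map, 0.0, seed=0)) == 0

    def test_negative_density_rejected(self, halves_map):
        with pytest.raises(ValueError):
            sample_initial_cells(halves_map, -1.0)

    def test_cells_stay_inside_their_droplet_footprint(self, halves_map):
        cells = sample_initial_cells(halves_map, 1e8, seed=3)
        centres = halves_map.droplet_centres().reshape(8, 7, 2)
        cx = centres[cells.droplet_row, cells.droplet_col, 0]
        cy = centres[cells.droplet_row, cells.droplet_col, 1]
        r = np.hypot(cells.x_um - cx, cells.y_um - cy)
        assert (r <= halves_map.droplet_diameter / 2 + 1e-9).all()

    def test_genotypes_follow_assignment(self, halves_map):
        cells = sample_initial_cells(halves_map, 1e8, seed=4)
        top = cells[cells.droplet_row < 4]
        bottom = cells[cells.droplet_row >= 4]
        assert (top.genotype == "A").all()
        assert (bottom.genotype == "B").all()


class TestSceneRender:
    def test_same_seed_gives_identical_scenes(self, halves_map):
        s1 = render_scene(halves_map, seed=9)
        s2 = render_scene(halves_map, seed=9)
        assert np.array_equal(s1.image.channels[0], s2.image.channels[0])
        assert np.array_equal(s1.image.channels[1], s2.image.channels[1])
        pd.testing.assert_frame_equal(s1.colonies, s2.colonies)

    def test_median_colony_diameter_near_target(self, halves_map):
        scene = render_scene(halves_map, seed=2)
        med = float(np.median(scene.colonies.diameter_um))
        assert abs(med - 15.0) < 1.0

    def test_noiseless_image_is_disks_on_constant_background(self, halves_map):
        noise = NoiseParams(noise_scale=0.0, background=7.0)
        scene = render_scene(halves_map, noise=noise, seed=5)
        px = scene.image.pixel_size
        for k, geno in enumerate(("A", "B")):
            sel = scene.colonies[scene.colonies.genotype == geno]
            expect = 7.0 + noise.amplitude * _render_disks(
                scene.image.shape,
                sel.x_um.to_numpy() / px - 0.5,
                sel.y_um.to_numpy() / px - 0.5,
                sel.diameter_um.to_numpy() / 2 / px,
            )
            assert np.allclose(scene.image.channels[k], expect)

    def test_rendering_conservation_no_clipping_loss(self, halves_map):
        scene = one_colony_per_droplet_scene(halves_map, seed=1)
        px = scene.image.pixel_size
        for _, col in scene.colonies.iterrows():
            ch = 0 if col.genotype == "A" else 1
            r = int(round(col.y_um / px - 0.5))
            c = int(round(col.x_um / px - 0.5))
            assert scene.image.channels[ch][r, c] > 50

    def test_label_honesty_single_channel_emission(self, halves_map):
        scene = one_colony_per_droplet_scene(halves_map, seed=1)
        bg = scene.noise.background
        px = scene.image.pixel_size
        for _, col in scene.colonies.iterrows():
            other = 1 if col.genotype == "A" else 0
            r = int(round(col.y_um / px - 0.5))
            c = int(round(col.x_um / px - 0.5))
            assert scene.image.channels[other][r, c] == pytest.approx(bg)

    def test_rotation_moves_colonies_but_keeps_count(self, halves_map):
        plain = render_scene(halves_map, seed=6)
        rot = render_scene(halves_map, rotation=30.0, seed=6)
        assert len(plain.colonies) == len(rot.colonies)
        assert not np.allclose(plain.colonies.x_um, rot.colonies.x_um)

    def test_degenerate_growth_params_rejected(self):
        with pytest.raises(ValueError, match="positive support"):
            GrowthParams(median_diameter=0.0)
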