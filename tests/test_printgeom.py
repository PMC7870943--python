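"""Print geometry: centre/size estimation, registration, neighbours."""

import numpy as np
import pandas as pd
import pytest

from printarray import (
    estimate_centre, estimate_side_length, isolate_print, make_printing_map,
    neighbour_distances, register_print, render_scene,
)
from printarray.printgeom import SQUARE_RADIUS_CONSTANT


def _table(xy):
    xy = np.asarray(xy, dtype=float)
    return pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1]})


def _rotate(xy, deg, about=(0.0, 0.0)):
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (np.asarray(xy) - about) @ R.T + about


class TestCentre:
    def test_square_corners_centre_at_origin(self):
        t = _table([(-1, -1), (1, -1), (1, 1), (-1, 1)])
        assert estimate_centre(t) == (0.0, 0.0)

    def test_single_colony_is_its_own_centre(self):
        assert estimate_centre(_table([(3, 7)])) == (3.0, 7.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_centre(_table(np.empty((0, 2))))

    def test_uniform_print_centre_recovered(self, halves_map):
        scene = render_scene(halves_map, seed=8)
        centre = estimate_centre(scene.colonies)
        truth = scene.print_centre()
        assert np.hypot(centre[0] - truth[0], centre[1] - truth[1]) < 5.0


class TestSideLength:
    def test_direct_formula_value(self):
        # r_bar = 100 => L = 600 / (sqrt 2 + ln(1 + sqrt 2))
        t = _table([(100, 0), (-100, 0), (0, 100), (0, -100)])
        L = estimate_side_length(t, (0.0, 0.0))
        assert L == pytest.approx(261.371, abs=0.001)

    def test_degenerate_all_at_centre(self):
        t = _table([(5, 5), (5, 5), (5, 5)])
        assert estimate_side_length(t, (5.0, 5.0)) == 0.0

    def test_uniform_square_recovery_within_2pct(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pos = rng.uniform(0, 1000.0, (1000, 2))
            errs.append(abs(estimate_side_length(_table(pos)) - 1000.0) / 1000.0)
        assert np.mean(errs) < 0.02

    def test_constant_matches_expected_radius_integral(self):
        # Monte-Carlo integral of E(r) over the unit square
        rng = np.random.default_rng(0)
        p = rng.uniform(-0.5, 0.5, (200_000, 2))
        assert np.hypot(p[:, 0], p[:, 1]).mean() == pytest.approx(
            SQUARE_RADIUS_CONSTANT, abs=5e-4
        )


class TestIsolation:
    @pytest.mark.parametrize("seed", range(3))
    def test_debris_removed_and_print_kept(self, halves_map, seed):
        scene = render_scene(halves_map, n_debris=5, seed=seed)
        truth = scene.colonies
        kept, _ = isolate_print(truth[["x_um", "y_um"]])
        kept_keys = set(zip(kept.x_um.round(6), kept.y_um.round(6)))
        removed = truth[
            [(round(x, 6), round(y, 6)) not in kept_keys
             for x, y in zip(truth.x_um, truth.y_um)]
        ]
        assert len(removed) == 5
        assert removed.is_debris.all()

    def test_clean_print_unchanged(self, halves_map):
        scene = render_scene(halves_map, seed=2)
        t = scene.colonies[["x_um", "y_um"]]
        kept, _ = isolate_print(t)
        assert len(kept) == len(t)

    def test_refined_centre_beats_initial_centre(self, halves_map):
        scene = render_scene(halves_map, n_debris=5, seed=1)
        t = scene.colonies[["x_um", "y_um"]]
        initial = estimate_centre(t)
        _, refined = isolate_print(t)
        truth = scene.print_centre()
        d0 = np.hypot(initial[0] - truth[0], initial[1] - truth[1])
        d1 = np.hypot(refined[0] - truth[0], refined[1] - truth[1])
        assert d1 < d0

    def test_overtight_margin_signalled(self):
        t = _table([(0, 0), (1000, 1000)])
        with pytest.raises(ValueError, match="margin_factor"):
            isolate_print(t, margin_factor=1e-6)


class TestRegistration:
    def test_axis_aligned_square_has_zero_rotation(self):
        rng = np.random.default_rng(0)
        t = _table(rng.uniform(0, 1000, (2000, 2)))
        theta, _, _ = register_print(t)
        assert abs(theta) < 0.5

    @pytest.mark.parametrize("alpha", [10.0, 100.0])
    def test_rotated_square_recovered_mod_90(self, alpha):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-500, 500, (800, 2))
        t = _table(_rotate(pos, alpha) + 1000)
        theta, _, _ = register_print(t)
        err = abs((theta - alpha + 45) % 90 - 45)
        assert err < 1.0

    def test_period_4_symmetry_of_descriptor(self):
        rng = np.random.default_rng(5)
        pos = rng.uniform(-500, 500, (800, 2))
        thetas = [
            register_print(_table(_rotate(pos, a) + 1000))[0]
            for a in (10.0, 100.0)
        ]
        assert thetas[0] == pytest.approx(thetas[1], abs=1e-9)

    def test_rotation_recovery_over_many_seeds(self):
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            alpha = rng.uniform(0, 360)
            pos = rng.uniform(-500, 500, (800, 2))
            theta, _, _ = register_print(_table(_rotate(pos, alpha) + 1000))
            errs.append(abs((theta - alpha + 45) % 90 - 45))
        assert max(errs) < 1.0

    def test_90_degree_rotation_swaps_registered_extent(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 1.0, (1500, 2)) * np.array([800.0, 400.0])
        _, _, ext0 = register_print(_table(pos))
        _, _, ext90 = register_print(_table(_rotate(pos, 90.0, (400, 200))))
        assert ext90[0] == pytest.approx(ext0[1], rel=0.02)
        assert ext90[1] == pytest.approx(ext0[0], rel=0.02)

    def test_collinear_points_rejected(self):
        t = _table([(i, 2 * i) for i in range(10)])
        with pytest.raises(ValueError, match="collinear|degenerate"):
            register_print(t)


class TestNeighbours:
    def test_square_grid_distances_cluster_at_pitch_and_diagonal(self):
        g = np.stack(np.meshgrid(np.arange(10) * 18.0,
                                 np.arange(10) * 18.0), -1).reshape(-1, 2)
        g += np.random.default_rng(1).normal(0, 0.1, g.shape)
        graph = neighbour_distances(_table(g))
        d = graph.interior_distances
        near_pitch = np.abs(d - 18.0) < 1.0
        near_diag = np.abs(d - 18.0 * np.sqrt(2)) < 1.0
        assert (near_pitch | near_diag).mean() > 0.95
        assert near_pitch.sum() > near_diag.sum()

    def test_hexagonal_lattice_all_interior_distances_equal_pitch(self):
        a = 20.0
        pts = []
        for i in range(8):
            for j in range(8):
                pts.append((j * a + (i % 2) * a / 2, i * a * np.sqrt(3) / 2))
        pts = np.asarray(pts) + np.random.default_rng(2).normal(0, 0.05,
                                                                (64, 2))
        graph = neighbour_distances(_table(pts))
        assert np.abs(graph.interior_distances - a).max() < 1.0

    def test_triangle_has_no_interior_edges(self):
        with pytest.warns(UserWarning, match="hull"):
            graph = neighbour_distances(_table([(0, 0), (10, 0), (5, 8)]))
        assert graph.interior_distances.size == 0
        assert len(graph.edges) == 3

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            neighbour_distances(_table([(0, 0), (1, 1)]))
        with pytest.raises(ValueError):
            neighbour_distances(_table([(0, 0), (1, 1), (2, 2), (3, 3)]))

    def test_printed_scene_neighbour_spacing_near_lattice(self, halves_map):
        # colonies seeded at ~70 per 110-µm droplet have centre-to-centre
        # spacings of a couple tens of µm
        scene = render_scene(halves_map, seed=4)
        graph = neighbour_distances(scene.colonies[["x_um", "y_um"]])
        med = float(np.median(graph.interior_distances))
        assert 5.0 < med < 30.0
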