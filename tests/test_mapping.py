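"""Nearest-neighbor potential mapping and concentration back-mapping."""

import numpy as np
import pytest

from hybridcell import mapping as mp
from hybridcell.errors import ConfigError


class TestNearest:
    def test_single_point_always_wins(self):
        idx = mp.build_index([[1.0, 2.0, 3.0]])
        for q in ([0, 0, 0], [100, -5, 2]):
            i, d = mp.nearest(idx, q)
            assert i == 0
            assert d == pytest.approx(np.linalg.norm(np.array(q, float)
                                                     - [1, 2, 3]))

    def test_exact_hit_distance_zero(self):
        pts = np.array([[0, 0, 0], [1, 1, 1], [2, 0, 1]], float)
        idx = mp.build_index(pts)
        i, d = mp.nearest(idx, [1, 1, 1])
        assert i == 1 and d == 0.0

    def test_345_triangle_distance(self):
        idx = mp.build_index([[3.0, 4.0, 0.0]])
        _, d = mp.nearest(idx, [0.0, 0.0, 0.0])
        assert d == pytest.approx(5.0)

    def test_duplicate_points_lowest_index_wins(self):
        pts = np.array([[5, 5, 5], [1, 1, 1], [1, 1, 1], [1, 1, 1]], float)
        idx = mp.build_index(pts)
        i, _ = mp.nearest(idx, [1.0, 1.0, 1.2])
        assert i == 1
        i2, _ = mp.nearest_bruteforce(idx, [1.0, 1.0, 1.2])
        assert i2 == 1

    def test_tree_matches_bruteforce_on_random_cloud(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(-1, 1, (1000, 3))
        queries = rng.uniform(-1.2, 1.2, (2000, 3))
        idx = mp.build_index(pts)
        it, dt = mp.nearest(idx, queries)
        ib, db = mp.nearest_bruteforce(idx, queries)
        np.testing.assert_array_equal(it, ib)
        np.testing.assert_allclose(dt, db, rtol=1e-12)

    def test_metric_order_changes_winner(self):
        """A crafted 3-point set where the L1 and L2 winners differ."""
        pts = np.array([[1.1, 0.0, 0.0],      # L1 dist 1.1, L2 dist 1.1
                        [0.8, 0.8, 0.0],      # L1 dist 1.6, L2 dist ~1.13
                        [9.0, 9.0, 9.0]], float)
        q = [0.0, 0.0, 0.0]
        i2, _ = mp.nearest(mp.build_index(pts, p=2.0), q)
        i1, _ = mp.nearest(mp.build_index(pts, p=1.0), q)
        assert i2 == 0 and i1 == 0
        pts2 = pts.copy()
        pts2[0] = [1.2, 0.0, 0.0]             # L2: 1.2 > 1.13 -> point 1
        i2b, _ = mp.nearest(mp.build_index(pts2, p=2.0), q)
        i1b, _ = mp.nearest(mp.build_index(pts2, p=1.0), q)
        assert i2b == 1 and i1b == 0
        # both metrics agree with their own brute force
        for p in (1.0, 2.0):
            idx = mp.build_index(pts2, p=p)
            assert mp.nearest(idx, q)[0] == \
                mp.nearest_bruteforce(idx, q)[0]

    def test_empty_source_rejected(self):
        with pytest.raises(ConfigError):
            mp.build_index(np.empty((0, 3)))


class TestMapPotentials:
    def _line_sources(self, n=10):
        pts = np.zeros((n, 3))
        pts[:, 0] = np.arange(n, dtype=float)
        return pts

    def test_coincident_target_all_modes(self):
        pts = self._line_sources()
        vals = np.arange(10, dtype=float) * 3.0
        idx = mp.build_index(pts)
        frame = mp.PotentialFrame(0.0, vals)
        for mode in ("nearest", "linear", "bilinear"):
            out = mp.map_potentials(idx, frame, pts[4][None, :], mode=mode,
                                    k=4, cutoff=10.0)
            assert out[0] == pytest.approx(vals[4])

    def test_midpoint_linear_interpolation(self):
        pts = np.array([[0, 0, 0], [1, 0, 0]], float)
        idx = mp.build_index(pts)
        frame = mp.PotentialFrame(0.0, np.array([0.0, 10.0]))
        out = mp.map_potentials(idx, frame, [[0.5, 0.3, 0.0]],
                                mode="linear", k=2, cutoff=5.0)
        assert out[0] == pytest.approx(5.0)

    def test_nearest_mode_idempotent(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 5, (50, 3))
        idx = mp.build_index(pts)
        frame = mp.PotentialFrame(0.0, rng.normal(size=50))
        targets = rng.uniform(0, 5, (200, 3))
        once = mp.map_potentials(idx, frame, targets, mode="nearest")
        # mapping the sources' own values again changes nothing
        again = mp.map_potentials(idx, mp.PotentialFrame(0.0, frame.values),
                                  targets, mode="nearest")
        np.testing.assert_array_equal(once, again)

    @pytest.mark.parametrize("mode,k", [("linear", 4), ("bilinear", 5)])
    def test_interpolation_is_convex_combination(self, mode, k):
        """Interpolated potentials never leave the [min, max] of the k
        contributing neighbors."""
        rng = np.random.default_rng(7)
        pts = self._line_sources(30) + rng.normal(0, 0.01, (30, 3))
        vals = rng.uniform(-80, 40, 30)
        idx = mp.build_index(pts)
        frame = mp.PotentialFrame(0.0, vals)
        targets = rng.uniform(0, 29, (100, 1)) * [1.0, 0, 0] \
            + rng.normal(0, 0.3, (100, 3))
        out = mp.map_potentials(idx, frame, targets, mode=mode, k=k,
                                cutoff=5.0)
        kd, ki = idx.tree.query(targets, k=k)
        lo = vals[ki].min(axis=1) - 1e-9
        hi = vals[ki].max(axis=1) + 1e-9
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_cutoff_falls_back_to_nearest(self):
        pts = self._line_sources()
        vals = np.arange(10, dtype=float)
        idx = mp.build_index(pts)
        frame = mp.PotentialFrame(0.0, vals)
        far = [[4.5, 50.0, 0.0]]
        out = mp.map_potentials(idx, frame, far, mode="linear", k=4,
                                cutoff=1.0)
        nn, _ = mp.nearest(idx, far)
        assert out[0] == vals[nn]

    def test_k_exceeding_sources_rejected(self):
        idx = mp.build_index(self._line_sources(3))
        frame = mp.PotentialFrame(0.0, np.zeros(3))
        with pytest.raises(ConfigError):
            mp.map_potentials(idx, frame, [[0, 0, 0]], mode="linear", k=5)


class TestBackMapping:
    def _quad_patch(self, n_tri=8, area_each=0.5):
        """Synthetic flat patch: n_tri right triangles of equal area."""
        tris = []
        verts = []
        for i in range(n_tri):
            base = len(verts)
            verts += [[i, 0, 0], [i + 1.0, 0, 0], [i, 1.0, 0]]
            tris.append([base, base + 1, base + 2])
        return (np.array(verts, float), np.array(tris),
                np.full(n_tri, area_each))

    def test_uniform_field_matched_areas_exact(self):
        verts, tris, areas = self._quad_patch()
        u = np.full(len(verts), 0.37)
        labels = np.zeros(len(tris), int)
        cyl = np.array([areas.sum()])
        out = mp.map_concentration_back(u, labels, areas, tris, cyl,
                                        np.array([-1]))
        assert out[0] == pytest.approx(0.37, abs=1e-12)

    def test_area_ratio_factor_literal(self):
        """Patch area 0.8x the cylinder area scales a uniform field by
        1.25 — the literal correction-factor reading."""
        verts, tris, areas = self._quad_patch()
        u = np.full(len(verts), 2.0)
        labels = np.zeros(len(tris), int)
        cyl = np.array([areas.sum() / 0.8])
        out = mp.map_concentration_back(u, labels, areas, tris, cyl,
                                        np.array([-1]))
        assert out[0] == pytest.approx(2.5)

    def test_linear_axial_field_gives_midvalue(self, cylinder_graph,
                                               cylinder_mesh):
        from hybridcell import meshgen, morphology
        surface, volume = cylinder_mesh
        model = morphology.build_compartments(cylinder_graph, 10.0)
        labels, pa, cyl = meshgen.assign_patches(surface, model)
        u = surface.vertices[:, 0]          # linear in the axial coordinate
        out = mp.map_concentration_back(u, labels,
                                        surface.triangle_areas(),
                                        surface.triangles, cyl,
                                        model.parent_indices)
        # surface average of x over the full cylinder surface is L/2;
        # the area-ratio factor rescales by pi*d*l/patch
        factor = cyl[0] / pa[0]
        assert out[0] == pytest.approx(5.0 * factor, rel=0.02)

    def test_constant_field_roundoff(self, cylinder_graph, cylinder_mesh):
        from hybridcell import meshgen, morphology
        surface, volume = cylinder_mesh
        model = morphology.build_compartments(cylinder_graph, 1.0)
        labels, pa, cyl = meshgen.assign_patches(surface, model)
        u = np.full(len(surface.vertices), 1.0)
        out = mp.map_concentration_back(u, labels,
                                        surface.triangle_areas(),
                                        surface.triangles, cyl,
                                        model.parent_indices)
        # constant in, constant-times-factor out, to accumulation roundoff
        np.testing.assert_allclose(out, cyl / pa, rtol=1e-12)
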