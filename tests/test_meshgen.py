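"""Surface/volume mesh generation, obstacles, quality, patches."""

import numpy as np
import pytest

from hybridcell import meshgen as G
from hybridcell import morphology as M
from hybridcell.cable1d import ObstacleSpec
from hybridcell.errors import MeshingError


class TestSurface:
    def test_cylinder_area_within_5_percent(self, cylinder_graph):
        s = G.surface_from_graph(cylinder_graph, n_circle=8)
        analytic = 2 * np.pi * 1.0 * 10.0 + 2 * np.pi * 1.0 ** 2
        assert s.area() == pytest.approx(analytic, rel=0.05)

    @pytest.mark.parametrize("fixture", ["cylinder_graph", "y_branch_graph",
                                         "soma_tree_graph"])
    def test_every_fixture_watertight_genus_zero(self, fixture, request):
        g = request.getfixturevalue(fixture)
        s = G.surface_from_graph(g, n_circle=10)
        assert s.is_watertight()
        assert s.euler_characteristic() == 2
        assert s.n_components() == 1

    def test_watertight_against_independent_checker(self, cylinder_mesh):
        trimesh = pytest.importorskip("trimesh")
        surface, _ = cylinder_mesh
        tm = trimesh.Trimesh(vertices=surface.vertices,
                             faces=surface.triangles, process=False)
        assert tm.is_watertight
        assert tm.is_winding_consistent
        assert surface.area() == pytest.approx(tm.area, rel=1e-9)

    def test_outward_orientation_positive_enclosed_volume(self,
                                                          cylinder_mesh):
        surface, volume = cylinder_mesh
        p = surface.vertices[surface.triangles]
        enclosed = np.einsum("ij,ij->i", p[:, 0],
                             np.cross(p[:, 1], p[:, 2])).sum() / 6.0
        assert enclosed > 0
        assert enclosed == pytest.approx(volume.volume(), rel=1e-9)


class TestVolume:
    def test_cylinder_volume_within_5_percent(self, cylinder_graph):
        s = G.surface_from_graph(cylinder_graph, n_circle=12)
        v = G.tetrahedralize(s)
        assert v.volume() == pytest.approx(np.pi * 10.0, rel=0.05)

    def test_all_tets_positively_oriented(self, cylinder_mesh):
        _, v = cylinder_mesh
        assert np.all(v.tet_volumes() > 0)

    def test_boundary_conforms_to_surface(self, cylinder_mesh):
        surface, volume = cylinder_mesh
        assert len(volume.boundary_faces) == len(surface.triangles)
        np.testing.assert_array_equal(
            surface.vertex_map[surface.triangles], volume.boundary_faces)

    def test_volume_error_decreases_under_refinement(self, cylinder_graph):
        analytic = np.pi * 10.0
        errs = []
        for nc in (8, 12, 16):
            s = G.surface_from_graph(cylinder_graph, n_circle=nc)
            v = G.tetrahedralize(s)
            errs.append(abs(v.volume() - analytic))
        assert errs[0] > errs[1] > errs[2]

    def test_non_watertight_input_rejected(self, cylinder_mesh):
        surface, _ = cylinder_mesh
        broken = G.SurfaceMesh(vertices=surface.vertices.copy(),
                               triangles=surface.triangles[:-3].copy(),
                               region=surface.region[:-3].copy())
        with pytest.raises(MeshingError):
            G.tetrahedralize(broken)


class TestObstacles:
    def test_h_zero_is_bitwise_noop(self, cylinder_graph):
        h = G.resolution_from_n_circle(cylinder_graph, 12)
        s0, v0 = G.build_mesh_pair(cylinder_graph, h)
        s1, v1 = G.build_mesh_pair(cylinder_graph, h,
                                   [ObstacleSpec(5.0, 1.0, 0.0, 0)])
        np.testing.assert_array_equal(v0.vertices, v1.vertices)
        np.testing.assert_array_equal(v0.tets, v1.tets)
        np.testing.assert_array_equal(s0.triangles, s1.triangles)

    def test_obstacle_radius_follows_hindrance(self, cylinder_graph):
        _, _, rec = G.insert_obstacle(cylinder_graph,
                                      ObstacleSpec(5.0, 1.0, 0.5, 0),
                                      n_circle=12)
        assert rec["radius_um"] == pytest.approx(0.5)   # H * r, r = 1 um

    def test_volume_deficit_matches_cylinder(self, cylinder_graph):
        spec = ObstacleSpec(arc_position=5.0, length=1.0, hindrance=0.5)
        _, _, rec = G.insert_obstacle(cylinder_graph, spec, n_circle=24)
        assert rec["volume_deficit_um3"] == \
            pytest.approx(rec["nominal_volume_um3"], rel=0.1)

    def test_outer_membrane_unaffected_by_insertion(self, cylinder_graph):
        h = G.resolution_from_n_circle(cylinder_graph, 16)
        s0, _ = G.build_mesh_pair(cylinder_graph, h)
        s1, _ = G.build_mesh_pair(cylinder_graph, h,
                                  [ObstacleSpec(5.0, 1.0, 0.5, 0)])
        mem0 = s0.area(G.REGION_MEMBRANE) + s0.area(G.REGION_CAP)
        mem1 = s1.area(G.REGION_MEMBRANE) + s1.area(G.REGION_CAP)
        assert mem0 == pytest.approx(mem1, rel=1e-9)
        assert s1.area(G.REGION_OBSTACLE) > 0

    def test_sealing_disc_splits_cytosol(self, cylinder_graph):
        spec = ObstacleSpec(arc_position=5.0, length=0.5, hindrance=1.0)
        s, v, _ = G.insert_obstacle(cylinder_graph, spec, n_circle=12)
        assert s.is_watertight()
        assert s.n_components() == 2

    def test_obstacle_longer_than_edge_rejected(self, cylinder_graph):
        from hybridcell.errors import ConfigError
        with pytest.raises(ConfigError):
            G.insert_obstacle(cylinder_graph,
                              ObstacleSpec(5.0, 50.0, 0.5, 0), n_circle=8)


class TestAspectRatio:
    def test_equilateral_triangle_scores_one(self):
        verts = np.array([[0, 0, 0], [1, 0, 0],
                          [0.5, np.sqrt(3) / 2, 0]], float)
        ar = G._tri_aspect_ratios(verts, np.array([[0, 1, 2]]))
        assert ar[0] == pytest.approx(1.0)

    def test_regular_tetrahedron_scores_one(self):
        verts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1],
                          [-1, -1, 1]], float)
        ar = G._tet_aspect_ratios(verts, np.array([[0, 1, 2, 3]]))
        assert ar[0] == pytest.approx(1.0)

    def test_needle_triangle_near_zero(self):
        # sides 1, 1, 1.999: nearly degenerate
        x = 1.999 / 2
        y = np.sqrt(1 - x ** 2)
        verts = np.array([[0, 0, 0], [1.999, 0, 0], [x, y, 0]], float)
        ar = G._tri_aspect_ratios(verts, np.array([[0, 1, 2]]))
        assert ar[0] < 0.1

    def test_degenerate_element_flagged(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], float)
        rep = G.aspect_ratio_report(
            G.SurfaceMesh(vertices=verts, triangles=np.array([[0, 1, 2]]),
                          region=np.zeros(1, int)))
        assert rep["min"] == 0.0 and rep["n_degenerate"] == 1

    @pytest.mark.parametrize("fixture", ["cylinder_graph", "y_branch_graph",
                                         "soma_tree_graph"])
    def test_fixture_tet_quality_meets_guideline(self, fixture, request):
        """Generated volume grids stay above the AR >= 0.1 stability
        guideline."""
        g = request.getfixturevalue(fixture)
        v = G.tetrahedralize(G.surface_from_graph(g, n_circle=10))
        rep = G.aspect_ratio_report(v)
        assert rep["min"] >= 0.1
        assert rep["max"] <= 1.0 + 1e-9


class TestPatches:
    def test_single_compartment_cylinder(self, cylinder_graph):
        s = G.surface_from_graph(cylinder_graph, n_circle=10)
        model = M.build_compartments(cylinder_graph, 10.0)
        labels, patch_areas, cyl_areas = G.assign_patches(s, model)
        noncap = s.region == G.REGION_MEMBRANE
        assert np.all(labels[noncap] == 0)
        lateral = s.triangle_areas()[noncap].sum()
        assert lateral == pytest.approx(cyl_areas[0], rel=0.05)

    def test_two_equal_compartments_symmetric(self, cylinder_graph):
        s = G.surface_from_graph(cylinder_graph, n_circle=10)
        model = M.build_compartments(cylinder_graph, 5.0)
        _, pa, _ = G.assign_patches(s, model)
        assert abs(pa[0] - pa[1]) / pa.mean() < 0.02

    def test_patches_partition_total_area(self, cylinder_graph):
        s = G.surface_from_graph(cylinder_graph, n_circle=10)
        model = M.build_compartments(cylinder_graph, 2.0)
        labels, pa, _ = G.assign_patches(s, model)
        assert np.all(labels >= 0)
        assert pa.sum() == pytest.approx(s.area(), rel=1e-12)

    def test_y_branch_every_compartment_has_patch(self, y_branch_graph):
        s = G.surface_from_graph(y_branch_graph, n_circle=12)
        model = M.build_compartments(y_branch_graph, 1.0)
        _, pa, _ = G.assign_patches(s, model)
        assert np.all(pa > 0)
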