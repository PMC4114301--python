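"""Finite-volume calcium reaction-diffusion solver."""

import numpy as np
import pytest

from hybridcell import calcium3d as C
from hybridcell import meshgen as G
from hybridcell import morphology as M
from hybridcell.errors import ConfigError


@pytest.fixture(scope="module")
def thin_cylinder_mesh():
    g = M.generate_synthetic("cylinder", length=10.0, radius=0.5)
    return G.build_mesh_pair(g, h=0.18)


class TestAssembly:
    def test_constants_in_kernel(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        A, _ = C.assemble(v, 0.1)
        u = np.full(len(v.vertices), 3.7)
        assert np.abs(A @ u).max() < 1e-12

    def test_symmetric_for_symmetric_tensor(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        A, _ = C.assemble(v, np.diag([0.1, 0.2, 0.05]))
        assert abs(A - A.T).max() < 1e-14

    def test_lumped_mass_sums_to_volume(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        _, Mv = C.assemble(v, 0.1)
        assert Mv.sum() == pytest.approx(v.volume(), rel=1e-9)
        assert np.all(Mv > 0)

    def test_zero_axial_diffusivity_decouples_axial_profile(
            self, thin_cylinder_mesh):
        """With d_x = 0 on the axis-aligned cylinder, an axial step
        profile generates no fluxes at all."""
        _, v = thin_cylinder_mesh
        A, _ = C.assemble(v, np.diag([0.0, 0.1, 0.1]))
        step = (v.vertices[:, 0] > 5.0).astype(float)
        assert np.abs(A @ step).max() < 1e-12

    def test_invalid_tensor_rejected(self):
        with pytest.raises(ConfigError):
            C.diffusion_tensor(np.diag([-1.0, 1.0, 1.0]))


class TestBufferEquilibrium:
    def test_zero_calcium_all_buffer_free(self):
        b, cab = C.buffer_equilibrium(0.0, C.BufferParams())
        assert b == pytest.approx(20.0)
        assert cab == pytest.approx(0.0)

    def test_reference_constants_give_expected_complex(self):
        """K_d = 0.24/0.09 ~ 2.667 uM; at c = 0.1 uM and B_total = 20 uM
        the bound complex is ~0.723 uM (algebraic root)."""
        p = C.BufferParams()
        assert p.k_d == pytest.approx(8.0 / 3.0)
        b, cab = C.buffer_equilibrium(0.1, p)
        assert cab == pytest.approx(0.7229, abs=2e-4)
        # detailed balance holds
        assert p.k_on * 0.1 * b == pytest.approx(p.k_off * cab, rel=1e-12)

    def test_saturation_limit(self):
        b, cab = C.buffer_equilibrium(1e9, C.BufferParams())
        assert b == pytest.approx(0.0, abs=1e-6)
        assert cab == pytest.approx(20.0, rel=1e-6)


class TestStepping:
    def test_equilibrium_is_steady_state(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        bp = C.BufferParams()
        sol = C.CalciumSolver(v, 0.1, bp)
        f = C.Field3D.uniform(len(v.vertices), 0.1, bp)
        out = sol.step(f, None, 0.1)
        np.testing.assert_allclose(out.c, f.c, atol=1e-12)
        np.testing.assert_allclose(out.b, f.b, atol=1e-12)

    def test_total_calcium_conserved_without_flux(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        bp = C.BufferParams()
        sol = C.CalciumSolver(v, 0.08, bp)
        x = v.vertices[:, 0]
        c0 = 0.1 + 0.3 * np.exp(-((x - 3.0) / 1.5) ** 2)
        b0, _ = C.buffer_equilibrium(c0, bp)
        f = C.Field3D(c=c0, b=b0)
        f._b_total = bp.b_total
        _, Mv = C.assemble(v, 0.08)
        before = C.total_calcium(f, Mv, bp)
        for _ in range(100):
            f = sol.step(f, None, 0.1)
        after = C.total_calcium(f, Mv, bp)
        assert abs(after - before) / before < 1e-10

    def test_cosine_mode_decays_at_fourier_rate(self, thin_cylinder_mesh):
        """c0 = 0.1 + 0.05 cos(pi x/L), D = 0.1 um^2/ms: the amplitude
        decays by e^{-D pi^2 t/L^2} (factor ~0.373 at 100 ms)."""
        _, v = thin_cylinder_mesh
        D, L, T, dt = 0.1, 10.0, 100.0, 0.5
        x = v.vertices[:, 0]
        f = C.Field3D(c=0.1 + 0.05 * np.cos(np.pi * x / L),
                      b=np.zeros_like(x))
        sol = C.CalciumSolver(v, D, None)
        for _ in range(int(T / dt)):
            f = sol.step(f, None, dt)
        _, Mv = C.assemble(v, D)
        mode = np.cos(np.pi * x / L)
        amp = (Mv * (f.c - 0.1)) @ mode / ((Mv * mode) @ mode)
        assert np.exp(-D * np.pi ** 2 * T / L ** 2) == \
            pytest.approx(0.3727, abs=2e-4)
        assert amp / 0.05 == pytest.approx(
            np.exp(-D * np.pi ** 2 * T / L ** 2), rel=0.02)

    def test_no_new_extrema_in_pure_diffusion(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        x = v.vertices[:, 0]
        f = C.Field3D(c=0.1 + 0.2 * np.sin(np.pi * x / 10.0),
                      b=np.zeros_like(x))
        sol = C.CalciumSolver(v, 0.1, None)
        lo, hi = f.c.min(), f.c.max()
        for _ in range(50):
            f = sol.step(f, None, 0.2)
            assert f.c.min() >= lo - 1e-9
            assert f.c.max() <= hi + 1e-9

    def test_boundary_flux_changes_mass_by_divergence_theorem(
            self, thin_cylinder_mesh):
        """One step with constant Phi on the membrane raises the total
        amount by dt * integral(Phi dA); doubling dt doubles it."""
        _, v = thin_cylinder_mesh
        sol = C.CalciumSolver(v, 0.1, None)
        _, Mv = C.assemble(v, 0.1)
        phi = 0.02    # uM*um/ms everywhere on the membrane
        w = v.boundary_vertex_areas(G.REGION_MEMBRANE) \
            + v.boundary_vertex_areas(G.REGION_CAP)
        f_ext = phi * w
        area = w.sum()
        for dt in (0.1, 0.2):
            f = C.Field3D.uniform(len(v.vertices), 0.1, None)
            before = C.total_calcium(f, Mv)
            sol2 = C.CalciumSolver(v, 0.1, None)
            out = sol2.step(f, f_ext, dt)
            gain = C.total_calcium(out, Mv) - before
            assert gain == pytest.approx(dt * phi * area, rel=1e-9)

    def test_buffer_bound_fraction_never_stored(self, thin_cylinder_mesh):
        """CaB is derived from the conservation law, so total buffer is
        exact by construction."""
        _, v = thin_cylinder_mesh
        bp = C.BufferParams()
        f = C.Field3D.uniform(len(v.vertices), 0.5, bp)
        np.testing.assert_allclose(f.b + f.cab, bp.b_total, rtol=0, atol=0)
        sol = C.CalciumSolver(v, 0.1, bp)
        out = sol.step(f, None, 0.1)
        np.testing.assert_allclose(out.b + out.cab, bp.b_total,
                                   rtol=0, atol=0)

    def test_stationary_buffer_supported(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        bp = C.BufferParams(d_b=0.0)
        sol = C.CalciumSolver(v, 0.1, bp)
        f = C.Field3D.uniform(len(v.vertices), 0.1, bp)
        out = sol.step(f, None, 0.1)
        np.testing.assert_allclose(out.c, f.c, atol=1e-12)


class TestConvergence:
    def test_second_order_in_space(self):
        """L2 self-convergence of the smooth cosine test across three
        nested refinements is ~2nd order (fitted slope >= 1.8)."""
        g = M.generate_synthetic("cylinder", length=10.0, radius=0.5)
        D, L, T, dt = 0.1, 10.0, 20.0, 0.05
        errs, hs = [], []
        for h in (0.4, 0.2, 0.1):
            _, v = G.build_mesh_pair(g, h)
            x = v.vertices[:, 0]
            f = C.Field3D(c=0.1 + 0.05 * np.cos(np.pi * x / L),
                          b=np.zeros_like(x))
            sol = C.CalciumSolver(v, D, None)
            for _ in range(int(T / dt)):
                f = sol.step(f, None, dt)
            exact = 0.1 + 0.05 * np.exp(-D * np.pi ** 2 * T / L ** 2) \
                * np.cos(np.pi * x / L)
            _, Mv = C.assemble(v, D)
            errs.append(np.sqrt(float(Mv @ (f.c - exact) ** 2)
                                / v.volume()))
            hs.append(h)
        slope = np.polyfit(np.log(hs), np.log(errs), 1)[0]
        assert slope >= 1.8
        assert errs[0] > errs[1] > errs[2]


class TestProbes:
    def test_vertex_probe_exact(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        vals = np.arange(len(v.vertices), dtype=float)
        loc = C.probe_locator(v, v.vertices[[10, 100]])
        out = C.probe(vals, loc)
        np.testing.assert_allclose(out, vals[[10, 100]], atol=1e-9)

    def test_uniform_field_uniform_probes(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        vals = np.full(len(v.vertices), 2.5)
        loc = C.probe_locator(v, [[5, 0, 0], [2, 0.1, 0.1], [8, -0.2, 0]])
        np.testing.assert_allclose(C.probe(vals, loc), 2.5)

    def test_linear_field_exact(self, thin_cylinder_mesh):
        _, v = thin_cylinder_mesh
        vals = v.vertices[:, 0]
        loc = C.probe_locator(v, [[3.21, 0.1, -0.05], [7.5, 0, 0.2]])
        np.testing.assert_allclose(C.probe(vals, loc), [3.21, 7.5],
                                   atol=1e-9)

    def test_outside_point_falls_back_to_nearest_vertex(
            self, thin_cylinder_mesh, caplog):
        import logging
        _, v = thin_cylinder_mesh
        with caplog.at_level(logging.WARNING, "hybridcell.calcium3d"):
            loc = C.probe_locator(v, [[50.0, 50.0, 50.0]])
        assert any("outside" in r.message for r in caplog.records)
        vals = v.vertices[:, 0]
        assert np.isfinite(C.probe(vals, loc)[0])
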