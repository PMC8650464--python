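import numpy as np
import pytest
from scipy.integrate import quad

from braintransport.discretization import build_mesh, interpolate_idw, tag_subdomains
from braintransport.solver import (
    FunctionSpace,
    SolverConfig,
    SourceSpec,
    TransportParams,
    analytic_point_source,
    sample_to_voxels,
    solve_transport,
)
from braintransport.subdomains import Subdomain

UMOL_PER_MM = 1e-3  # 1 mM = 1e-3 µmol/mm³


def _cube_mesh(n, size_mm, tag=1):
    mesh = build_mesh(np.ones((n, n, n), bool), voxel_size=size_mm / n)
    mesh.cell_tags[:] = tag
    return mesh


def _total_amount(mesh, field, frame, order=1):
    space = FunctionSpace(mesh, order)
    deff = np.ones(mesh.n_cells)
    _, M, lumped = space.assemble(deff)
    if order == 1:
        return float(lumped @ field.values[:, frame]) * UMOL_PER_MM
    return float((M @ field.values[:, frame]).sum()) * UMOL_PER_MM


class TestAnalyticPointSource:
    def test_instantaneous_vanishes_late(self):
        c1 = analytic_point_source(0.1, 1.0, 1.0, Q=1.0, mode="instantaneous")
        c2 = analytic_point_source(0.1, 1.0, 1e6, Q=1.0, mode="instantaneous")
        assert c2 < 1e-6 * c1

    def test_instantaneous_integrates_to_Q(self):
        # quadrature oracle: ∫ 4πr² c(r) dr = Q
        D, t, Q = 0.05, 2.0, 0.7

        def integrand(r):
            c = analytic_point_source(D, r, t, Q=Q, mode="instantaneous")
            return 4.0 * np.pi * r ** 2 * c * UMOL_PER_MM

        total, _ = quad(integrand, 1e-9, 10.0)
        assert total == pytest.approx(Q, rel=1e-6)

    def test_continuous_steady_state(self):
        D, q, r = 0.1, 0.034, 0.5
        late = analytic_point_source(D, r, 1e12, q=q, mode="continuous")
        steady_mM = q / (4.0 * np.pi * D * r) * 1e3  # erfc -> 1
        assert late == pytest.approx(steady_mM, rel=1e-6)

    def test_singularity_rejected(self):
        with pytest.raises(ValueError):
            analytic_point_source(0.1, 0.0, 1.0, q=1.0)

    def test_bad_mode(self):
        with pytest.raises(ValueError, match="mode"):
            analytic_point_source(0.1, 1.0, 1.0, q=1.0, mode="wat")


class TestSolveTransport:
    def test_zero_source(self):
        mesh = _cube_mesh(6, 1.0)
        src = SourceSpec(location=(0.5, 0.5, 0.5), rate=0.0, start=0.0, stop=1.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [0.0, 5.0, 10.0])
        assert np.all(f.values == 0.0)

    def test_mass_conservation_impulse(self):
        # short source, then no-flux coasting: ∫c dV equals Q for all frames
        mesh = _cube_mesh(10, 2.0)
        src = SourceSpec(location=(1.0, 1.0, 1.0), rate=0.2, start=0.0, stop=1.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.05}), src,
                            [2.0, 5.0, 10.0, 20.0], SolverConfig(dt=0.25))
        Q = src.total_amount
        amounts = [_total_amount(mesh, f, k) for k in range(4)]
        np.testing.assert_allclose(amounts, Q, rtol=1e-6)

    def test_mass_matches_partial_infusion(self):
        mesh = _cube_mesh(8, 1.6)
        src = SourceSpec(location=(0.8, 0.8, 0.8), rate=0.034, start=0.0, stop=20.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.05}), src,
                            [10.0, 30.0], SolverConfig(dt=0.5))
        assert _total_amount(mesh, f, 0) == pytest.approx(0.034 * 10.0, rel=1e-9)
        assert _total_amount(mesh, f, 1) == pytest.approx(0.034 * 20.0, rel=1e-9)

    def test_initial_condition_zero(self):
        mesh = _cube_mesh(6, 1.0)
        src = SourceSpec(location=(0.5, 0.5, 0.5), rate=0.1, start=0.0, stop=5.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [0.0, 1.0])
        assert np.all(f.values[:, 0] == 0.0)
        assert f.values[:, 1].max() > 0.0

    def test_source_outside_mesh_rejected(self):
        mesh = _cube_mesh(6, 1.0)
        src = SourceSpec(location=(5.0, 5.0, 5.0), rate=0.1, start=0.0, stop=5.0)
        with pytest.raises(ValueError, match="source"):
            solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [1.0])

    def test_unsorted_times_rejected(self):
        mesh = _cube_mesh(4, 1.0)
        src = SourceSpec(location=(0.5, 0.5, 0.5), rate=0.1, start=0.0, stop=5.0)
        with pytest.raises(ValueError):
            solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [5.0, 1.0])

    def test_symmetry(self):
        n = 8
        mesh = _cube_mesh(n, 1.6)
        src = SourceSpec(location=(0.8, 0.8, 0.8), rate=0.1, start=0.0, stop=5.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.05}), src, [4.0])
        grid = f.values[:, 0].reshape(n + 1, n + 1, n + 1)  # full cube: dense nodes
        np.testing.assert_allclose(grid, grid[::-1], atol=1e-9 * grid.max())
        np.testing.assert_allclose(grid, np.swapaxes(grid, 0, 1),
                                   atol=1e-9 * grid.max())

    def test_comparison_principle_at_source(self):
        mesh = _cube_mesh(8, 1.6)
        src = SourceSpec(location=(0.8, 0.8, 0.8), rate=0.1, start=0.0, stop=10.0)
        peak = []
        for D in (0.02, 0.08, 0.32):
            f = solve_transport(mesh, TransportParams(deff={1: D}), src, [5.0])
            sd = f.diagnostics["source_dof"]
            peak.append(f.values[sd, 0])
        assert peak[0] > peak[1] > peak[2]

    def test_oracle_continuous_source(self):
        # uniform domain continuous release vs q/(4πDr)·erfc(r/2√(Dt))
        n, L = 20, 3.0
        h = L / n
        mesh = _cube_mesh(n, L)
        D, q = 0.05, 0.034
        src = SourceSpec(location=(L / 2, L / 2, L / 2), rate=q, start=0.0, stop=99.0)
        f = solve_transport(mesh, TransportParams(deff={1: D}), src, [3.0],
                            SolverConfig(dt=0.1))
        r = np.linalg.norm(f.coords - L / 2, axis=1)
        sel = (r >= 3 * np.sqrt(3) * h) & (r <= 1.1)
        exact = analytic_point_source(D, r[sel], 3.0, q=q, mode="continuous")
        rel = np.abs(f.values[sel, 0] - exact) / exact
        assert np.median(rel) < 0.05
        assert rel.max() < 0.12

    def test_convergence_under_refinement(self):
        D, q, L, t = 0.05, 0.034, 3.0, 3.0
        errs = []
        for n, dt in ((10, 0.4), (20, 0.1)):
            h = L / n
            mesh = _cube_mesh(n, L)
            src = SourceSpec(location=(L / 2, L / 2, L / 2), rate=q, start=0.0,
                             stop=99.0)
            f = solve_transport(mesh, TransportParams(deff={1: D}), src, [t],
                                SolverConfig(dt=dt))
            r = np.linalg.norm(f.coords - L / 2, axis=1)
            sel = (r >= 0.8) & (r <= 1.1)
            exact = analytic_point_source(D, r[sel], t, q=q, mode="continuous")
            errs.append(np.abs(f.values[sel, 0] - exact).max() / exact.max())
        assert errs[1] < errs[0]

    def test_min_concentration_reported(self):
        mesh = _cube_mesh(6, 1.0)
        src = SourceSpec(location=(0.5, 0.5, 0.5), rate=0.1, start=0.0, stop=5.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [2.0])
        assert "min_concentration_mM" in f.diagnostics
        assert f.diagnostics["min_concentration_mM"] <= 0.0


class TestBlockedSubdomains:
    def test_artery_blocks_transport(self, small_gt, true_params, small_source):
        # fixed artery/ventricle Deff = blocked_fraction x BT
        assert true_params.deff_for_tag(int(Subdomain.ARTERY)) == pytest.approx(
            1e-8 * 0.10
        )
        assert true_params.deff_for_tag(int(Subdomain.VENTRICLE)) == pytest.approx(
            1e-8 * 0.10
        )

    def test_unknown_tag_rejected(self):
        with pytest.raises(KeyError):
            TransportParams().deff_for_tag(77)

    def test_nonpositive_deff_rejected(self):
        with pytest.raises(ValueError):
            TransportParams(deff={1: 0.0})


class TestSecondOrderElements:
    def test_mass_conservation_q2(self):
        mesh = _cube_mesh(5, 1.0)
        src = SourceSpec(location=(0.5, 0.5, 0.5), rate=0.1, start=0.0, stop=1.0)
        f = solve_transport(mesh, TransportParams(deff={1: 0.05}), src,
                            [2.0, 5.0], SolverConfig(dt=0.25, element_order=2))
        a = [_total_amount(mesh, f, k, order=2) for k in range(2)]
        np.testing.assert_allclose(a, 0.1, rtol=1e-6)

    def test_q2_matches_q1_on_smooth_field(self):
        mesh = _cube_mesh(8, 1.6)
        src = SourceSpec(location=(0.8, 0.8, 0.8), rate=0.05, start=0.0, stop=10.0)
        f1 = solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [5.0],
                             SolverConfig(dt=0.25, element_order=1))
        f2 = solve_transport(mesh, TransportParams(deff={1: 0.1}), src, [5.0],
                             SolverConfig(dt=0.25, element_order=2))
        # compare at shared corner nodes, away from the source
        sp2 = FunctionSpace(mesh, 2)
        vals2, _ = sp2.evaluate(f2.values[:, 0], f1.coords)
        r = np.linalg.norm(f1.coords - np.array(src.location), axis=1)
        far = r > 0.5
        denom = np.abs(f1.values[far, 0]).max()
        assert np.abs(f1.values[far, 0] - vals2[far]).max() / denom < 0.10


class TestSampleToVoxels:
    def test_constant_field(self):
        n = 6
        mesh = _cube_mesh(n, 1.2)
        space = FunctionSpace(mesh, 1)
        from braintransport.discretization import NodalField

        field = NodalField(values=np.full((space.n_dofs, 1), 2.5),
                           coords=space.coords, times=np.array([0.0]))
        vol, inside = sample_to_voxels(field, mesh, (n, n, n), voxel_size=0.2)
        assert inside.all()
        np.testing.assert_allclose(vol, 2.5, rtol=1e-12)

    def test_outside_mesh_zero(self):
        mask = np.zeros((6, 6, 6), bool)
        mask[:3] = True
        mesh = build_mesh(mask, voxel_size=0.2)
        mesh.cell_tags[:] = 1
        space = FunctionSpace(mesh, 1)
        from braintransport.discretization import NodalField

        field = NodalField(values=np.ones((space.n_dofs, 1)), coords=space.coords,
                           times=np.array([0.0]))
        vol, inside = sample_to_voxels(field, mesh, (6, 6, 6), voxel_size=0.2)
        assert inside[:3].all() and not inside[4:].any()
        assert np.all(vol[4:] == 0.0)

    def test_idw_roundtrip_smooth(self):
        # smooth voxel field -> nodes (IDW) -> back to voxels within 2%
        n, h = 16, 0.2
        idx = np.stack(np.meshgrid(*[np.arange(n) + 0.5] * 3, indexing="ij"),
                       axis=-1) * h
        vol = 1.0 + np.sin(idx[..., 0]) * np.cos(idx[..., 1]) * 0.2 + 0.1 * idx[..., 2]
        mesh = build_mesh(np.ones((n, n, n), bool), voxel_size=h)
        nodal = interpolate_idw(vol, mesh, voxel_size=h)
        from braintransport.discretization import NodalField

        space = FunctionSpace(mesh, 1)
        field = NodalField(values=nodal[:, None], coords=space.coords,
                           times=np.array([0.0]))
        back, _ = sample_to_voxels(field, mesh, (n, n, n), voxel_size=h)
        inner = (slice(2, -2),) * 3
        rel = np.abs(back[..., 0][inner] - vol[inner]) / np.abs(vol[inner])
        assert rel.max() < 0.02
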