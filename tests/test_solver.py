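import numpy as np
import pytest
from dataclasses import replace

import scipy.sparse as sp

from neuriteflow import (ConcentrationState, MorphologySpec, SimulationParams,
                         build_unit_graph, compute_velocity, decompose,
                         generate_morphology, run_to_steady_state,
                         solve_transport)
from neuriteflow.solver import build_operators, solve_network, merge_network
from conftest import make_chain_graph


def _uniform_state(n, c0=1.0, params=None):
    p = params or SimulationParams()
    ratio = p.k_plus / p.kp_plus
    return ConcentrationState(np.full(n, c0), np.full(n, ratio * c0))


class TestVelocity:
    def test_inlet_center_speed_is_u_i(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        sel = pipe_graph.section_nodes(pipe_graph.inlet_section)
        center = sel[pipe_graph.rfrac[sel] == 0][0]
        assert np.isclose(np.linalg.norm(vf.vectors[center]), params.u_i)

    def test_wall_nodes_are_static(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        wall = pipe_graph.rfrac == 1.0
        assert np.allclose(vf.vectors[wall], 0.0)

    def test_parabolic_profile(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        s = pipe_graph.inlet_section
        sel = pipe_graph.section_nodes(s)
        speeds = np.linalg.norm(vf.vectors[sel], axis=1)
        expected = vf.u_sec[s] * (1 - pipe_graph.rfrac[sel] ** 2)
        assert np.allclose(speeds, expected)

    def test_flux_split_preserves_parent_flux(self, bif_graph, params):
        vf = compute_velocity(bif_graph, params)
        q_par = vf.flux[3]
        q_kids = vf.flux[4] + vf.flux[7]
        assert abs(q_par - q_kids) <= 1e-12 * abs(q_par)

    @pytest.mark.parametrize("seed", range(20))
    def test_flux_conservation_random_geometries(self, seed, params):
        rng = np.random.default_rng(seed)
        m = generate_morphology(MorphologySpec(
            n_bifurcations=1, radius_root=float(rng.uniform(0.6, 1.4)),
            taper_ratio=float(rng.uniform(0.6, 1.0)), seed=seed))
        sg = decompose(m)
        g = build_unit_graph(next(u for u in sg.units if u.kind == "bifurcation"))
        vf = compute_velocity(g, params)
        assert abs(vf.flux[3] - (vf.flux[4] + vf.flux[7])) <= 1e-12 * vf.flux[3]

    def test_matched_child_area_keeps_speed(self, params):
        # children at radius parent/sqrt(2): area is conserved, so the
        # centerline speed carries over unchanged
        from test_graph_build import _symmetric_bifurcation
        from neuriteflow.graph_build import build_bifurcation_graph

        b = _symmetric_bifurcation(radius=1.0)
        for sec_list in b.child_sections:
            for s in sec_list:
                s.radius = 1.0 / np.sqrt(2.0)
        g = build_bifurcation_graph(b)
        vf = compute_velocity(g, params)
        assert np.isclose(vf.u_sec[4], vf.u_sec[3])


class TestTransport:
    def test_uniform_balanced_state_is_stationary(self, pipe_graph, bif_graph,
                                                  params):
        for g in (pipe_graph, bif_graph):
            vf = compute_velocity(g, params)
            init = _uniform_state(g.n_nodes, c0=params.c_in)
            traj = solve_transport(g, params, vf, init, 5)
            dev = max(np.abs(traj[-1].c0 - init.c0).max(),
                      np.abs(traj[-1].c_plus - init.c_plus).max())
            assert dev < 1e-10

    def test_pure_diffusion_conserves_mass_closed(self, pipe_graph):
        p = SimulationParams(k_plus=0, k_minus=0, kp_plus=0, kp_minus=0,
                             u_i=0.0, c_in=None)
        vf = compute_velocity(pipe_graph, p)
        rng = np.random.default_rng(0)
        init = ConcentrationState(rng.random(pipe_graph.n_nodes),
                                  np.zeros(pipe_graph.n_nodes))
        total0 = init.c0.sum()
        traj = solve_transport(pipe_graph, p, vf, init, 1000, closed=True)
        assert abs(traj[-1].c0.sum() - total0) <= 1e-10 * total0

    def test_advected_pulse_speed(self, pipe_graph):
        p = SimulationParams(D=0.0, k_plus=0, k_minus=0, kp_plus=0,
                             kp_minus=0, c_in=None)
        vf = compute_velocity(pipe_graph, p)
        g = pipe_graph
        cp = np.where(g.node_section == 1, 1.0, 0.0)
        init = ConcentrationState(np.zeros(g.n_nodes), cp.copy())
        n = 40
        traj = solve_transport(g, p, vf, init, n, closed=True)
        speeds = np.linalg.norm(vf.vectors, axis=1)
        expected = (cp * speeds).sum() / cp.sum() * n * p.dt
        axis = g.section_centers[-1] - g.section_centers[0]
        axis /= np.linalg.norm(axis)
        com0 = (g.positions @ axis * cp).sum() / cp.sum()
        w = traj[-1].c_plus
        com1 = (g.positions @ axis * w).sum() / w.sum()
        assert abs((com1 - com0) - expected) <= 0.05 * expected

    def test_non_negativity(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        rng = np.random.default_rng(3)
        init = ConcentrationState(rng.random(pipe_graph.n_nodes),
                                  rng.random(pipe_graph.n_nodes))
        traj = solve_transport(pipe_graph, params, vf, init, 100)
        for st in traj:
            assert st.c0.min() >= -1e-12 and st.c_plus.min() >= -1e-12

    def test_instability_raises(self, pipe_graph, params):
        # an anti-diffusive operator (sign-flipped Laplacian) grows grid
        # modes exponentially, which must trip the divergence guard
        from neuriteflow.solver import StabilityError, Operators
        vf = compute_velocity(pipe_graph, params)
        ops = build_operators(pipe_graph, vf, params)
        bad = Operators(lap=-ops.lap, adv=ops.adv,
                        inlet_nodes=ops.inlet_nodes,
                        outlet_dst=ops.outlet_dst, outlet_src=ops.outlet_src,
                        min_edge=ops.min_edge, interior=ops.interior)
        init = ConcentrationState(
            np.random.default_rng(0).random(pipe_graph.n_nodes),
            np.zeros(pipe_graph.n_nodes))
        with pytest.raises(StabilityError):
            solve_transport(pipe_graph, params, vf, init, 2000, ops=bad)


class TestSteadyState:
    def test_stationary_init_steady_immediately(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        init = _uniform_state(pipe_graph.n_nodes, c0=params.c_in)
        res = run_to_steady_state(pipe_graph, params, vf, init, tol=1e-6,
                                  max_time=50.0)
        assert res.steady
        assert res.steady_time == pytest.approx(params.dt)

    def test_zero_tolerance_runs_to_max_time(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        init = _uniform_state(pipe_graph.n_nodes, c0=params.c_in)
        res = run_to_steady_state(pipe_graph, params, vf, init, tol=0.0,
                                  max_time=1.0)
        assert not res.steady
        assert res.steady_time == pytest.approx(1.0)

    def test_dt_self_convergence(self, pipe_graph, params):
        vf = compute_velocity(pipe_graph, params)
        init = ConcentrationState.zeros(pipe_graph.n_nodes)
        out = {}
        for dt in (0.1, 0.05):
            p = replace(params, dt=dt)
            res = run_to_steady_state(pipe_graph, p, vf, init, tol=3e-5,
                                      max_time=400.0)
            assert res.steady
            out[dt] = res.trajectory[-1].c0
        diff = np.abs(out[0.1] - out[0.05]).max() / np.abs(out[0.05]).max()
        assert diff < 0.01


class TestGridConvergence:
    def test_chain_steady_state_converges_to_dense_1d_solution(self):
        """On a 1D chain domain the solver must converge with grid
        refinement to an independently computed dense-grid steady solution
        of the two-field model."""
        # moderate Peclet number so the first-order upwind error dominates
        # the refinement study
        L = 6.0
        p = SimulationParams(u_i=0.5)

        def steady(n):
            g = make_chain_graph(n, L)
            vf = compute_velocity(g, p)
            init = ConcentrationState.zeros(n)
            res = run_to_steady_state(g, p, vf, init, tol=1e-8, max_time=400.0)
            assert res.steady
            return np.linspace(0, L, n), res.trajectory[-1]

        # independent oracle: direct sparse solve of the stationary
        # discretized equations on a dense grid (central diffusion, upwind
        # advection, Dirichlet inlet, zero-gradient outlet)
        nf = 1201
        x = np.linspace(0, L, nf)
        h = x[1] - x[0]
        D, kp, kpp, u = p.D, p.k_plus, p.kp_plus, p.u_i
        n2 = 2 * nf
        A = sp.lil_matrix((n2, n2))
        rhs = np.zeros(n2)
        for i in range(nf):
            if i == 0:
                A[i, i] = 1.0
                rhs[i] = p.c_in
                A[nf + i, nf + i] = 1.0
                rhs[nf + i] = p.lambda_in * p.c_in
                continue
            if i == nf - 1:
                A[i, i], A[i, i - 1] = 1.0, -1.0
                A[nf + i, nf + i], A[nf + i, nf + i - 1] = 1.0, -1.0
                continue
            A[i, i - 1] += D / h**2
            A[i, i + 1] += D / h**2
            A[i, i] += -2 * D / h**2 - kp
            A[i, nf + i] += kpp
            A[nf + i, nf + i - 1] += u / h
            A[nf + i, nf + i] += -u / h - kpp
            A[nf + i, i] += kp
        sol = sp.linalg.spsolve(A.tocsr(), rhs)
        c0_ref, cp_ref = sol[:nf], sol[nf:]

        errs = []
        for n in (11, 21, 41):
            xs, st = steady(n)
            err = max(np.abs(st.c0 - np.interp(xs, x, c0_ref)).max(),
                      np.abs(st.c_plus - np.interp(xs, x, cp_ref)).max())
            errs.append(err)
        assert errs[0] > errs[1] > errs[2]


class TestNetworkSolve:
    def test_merged_interfaces_single_valued(self, y_structure, params):
        graphs = {u.unit_id: build_unit_graph(u) for u in y_structure.units}
        traj, merged = solve_network(y_structure, graphs, params, 10)
        total = sum(g.n_nodes for g in graphs.values())
        dups = 17 * len(y_structure.adjacency)
        assert merged.graph.n_nodes == total - dups

    def test_network_inlet_holds_bc(self, y_structure, params):
        graphs = {u.unit_id: build_unit_graph(u) for u in y_structure.units}
        traj, merged = solve_network(y_structure, graphs, params, 5)
        root = y_structure.root_unit
        g = graphs[root]
        inlet = merged.node_maps[root][g.section_nodes(g.inlet_section)]
        assert np.allclose(traj[-1].c0[inlet], params.c_in)
        assert np.allclose(traj[-1].c_plus[inlet],
                           params.lambda_in * params.c_in)


class TestBidirectionalMode:
    def test_balanced_three_species_state_is_stationary(self, pipe_graph):
        p = SimulationParams(unidirectional=False, lambda_out=2.0, c_out=1.0)
        vf = compute_velocity(pipe_graph, p)
        n = pipe_graph.n_nodes
        c0 = np.full(n, 1.0)
        init = ConcentrationState(c0, 2.0 * c0, c_minus=2.0 * c0)
        traj = solve_transport(pipe_graph, p, vf, init, 5)
        assert np.abs(traj[-1].c0 - 1.0).max() < 1e-10
        assert np.abs(traj[-1].c_minus - 2.0).max() < 1e-10


class TestTrajectoryIO:
    def test_hdf5_round_trip(self, tmp_path, pipe_graph, params):
        from neuriteflow.solver import (load_trajectory_hdf5,
                                        save_trajectory_hdf5,
                                        steady_state_to_csv)
        vf = compute_velocity(pipe_graph, params)
        init = ConcentrationState.zeros(pipe_graph.n_nodes)
        traj = solve_transport(pipe_graph, params, vf, init, 3)
        path = tmp_path / "traj.h5"
        save_trajectory_hdf5(path, traj, unit_id=4, mode="w")
        again = load_trajectory_hdf5(path, unit_id=4)
        assert len(again) == len(traj)
        assert np.allclose(again[-1].c0, traj[-1].c0)
        assert again[-1].time == pytest.approx(traj[-1].time)
        csv = tmp_path / "steady.csv"
        steady_state_to_csv(csv, pipe_graph, traj[-1])
        assert csv.read_text().startswith("node,")


class TestEdgeListExport:
    def test_edge_list_file(self, tmp_path, pipe_graph):
        from neuriteflow.graph_build import export_edge_list
        path = tmp_path / "edges.txt"
        export_edge_list(pipe_graph, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == len(pipe_graph.edges)
        i, j, ell = lines[0].split()
        assert float(ell) > 0
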