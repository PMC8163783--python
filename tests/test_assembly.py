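import numpy as np
import pytest
from dataclasses import replace

from neuriteflow import (AssemblyModel, ConcentrationState, GlobalPrediction,
                         MorphologySpec, SimulationParams, SimulatorModel,
                         assemble_step, assembly_loss, build_unit_graph,
                         decompose, generate_morphology, make_features,
                         predict_network, rollout)
from neuriteflow.assembly import footprint, interface_discrepancy, _pack, _unpack


@pytest.fixture(scope="module")
def network():
    m = generate_morphology(MorphologySpec(n_bifurcations=1, seed=21))
    sg = decompose(m, max_pipe_sections=50)
    graphs = {u.unit_id: build_unit_graph(u) for u in sg.units}
    return sg, graphs


def _random_prediction(graphs, seed=0):
    rng = np.random.default_rng(seed)
    return GlobalPrediction({uid: rng.random((g.n_nodes, 2))
                             for uid, g in graphs.items()})


def _agreeing_prediction(sg, graphs, seed=0):
    gp = _random_prediction(graphs, seed)
    for a, b, ifid in sg.adjacency:
        ia = footprint(graphs[a], ifid)[0]
        ib = footprint(graphs[b], ifid)[0]
        gp.fields[b][ib] = gp.fields[a][ia]
    return gp


class TestAssembleStep:
    def test_identity_init_is_consistency_fixed_point(self, network):
        sg, graphs = network
        model = AssemblyModel(identity_init=True, rng=np.random.default_rng(0))
        gp = _agreeing_prediction(sg, graphs)
        out = assemble_step(model, sg, graphs, gp)
        for uid in graphs:
            assert np.allclose(out.fields[uid], gp.fields[uid], atol=1e-14)

    def test_interfaces_single_valued_after_assembly(self, network):
        sg, graphs = network
        model = AssemblyModel(rng=np.random.default_rng(1), identity_init=False)
        out = assemble_step(model, sg, graphs, _random_prediction(graphs))
        assert interface_discrepancy(out, sg, graphs) < 1e-14

    def test_missing_unit_prediction_raises(self, network):
        sg, graphs = network
        model = AssemblyModel()
        gp = _random_prediction(graphs)
        del gp.fields[next(iter(graphs))]
        with pytest.raises(ValueError, match="no prediction"):
            assemble_step(model, sg, graphs, gp)

    def test_component_dispatch_counts(self, network, monkeypatch):
        """A bifurcation flanked by pipes invokes only the pipe-bifurcation
        component, twice per shared interface."""
        sg, graphs = network
        model = AssemblyModel(rng=np.random.default_rng(0))
        calls = {k: 0 for k in model.components}
        for key, comp in model.components.items():
            orig = comp.forward

            def counted(x, cache=None, _k=key, _o=orig):
                calls[_k] += 1
                return _o(x, cache)

            monkeypatch.setattr(comp, "forward", counted)
        assemble_step(model, sg, graphs, _random_prediction(graphs))
        n_pb_interfaces = len(sg.adjacency)
        assert calls[("bifurcation", "pipe")] == 2 * n_pb_interfaces
        assert calls[("pipe", "pipe")] == 0
        assert calls[("bifurcation", "bifurcation")] == 0

    def test_matches_independent_reimplementation(self, network):
        """Resolved values equal a from-scratch gather-concatenate-MLP-average
        pass with the same weights."""
        sg, graphs = network
        model = AssemblyModel(rng=np.random.default_rng(3), identity_init=False)
        gp = _random_prediction(graphs, seed=5)
        out = assemble_step(model, sg, graphs, gp)

        # independent re-implementation
        upd = {uid: [np.zeros_like(gp.fields[uid]),
                     np.zeros(len(gp.fields[uid]))] for uid in graphs}
        for a, b, ifid in sg.adjacency:
            for cur, oth in ((a, b), (b, a)):
                gc, go = graphs[cur], graphs[oth]
                ic, ac = footprint(gc, ifid)
                io = footprint(go, ifid)[0]
                x = np.concatenate([gp.fields[cur][ic][:, 0], gp.fields[cur][ic][:, 1],
                                    gp.fields[cur][ac][:, 0], gp.fields[cur][ac][:, 1],
                                    gp.fields[oth][io][:, 0], gp.fields[oth][io][:, 1]])
                h = x[None, :]
                comp = model.component(gc.kind, go.kind)
                for k in range(comp.n_layers):
                    h = h @ comp.W[k] + comp.b[k]
                    if k < comp.n_layers - 1:
                        h = np.maximum(h, 0)
                delta = h[0]
                d_if = np.column_stack([delta[0:17], delta[17:34]])
                d_adj = np.column_stack([delta[34:51], delta[51:68]])
                upd[cur][0][ic] += gp.fields[cur][ic] + d_if
                upd[cur][0][ac] += gp.fields[cur][ac] + d_adj
                upd[cur][1][ic] += 1
                upd[cur][1][ac] += 1
        ref = {uid: gp.fields[uid].copy() for uid in graphs}
        for uid in graphs:
            m = upd[uid][1] > 0
            ref[uid][m] = upd[uid][0][m] / upd[uid][1][m, None]
        for a, b, ifid in sorted(sg.adjacency, key=lambda t: t[2]):
            ia = footprint(graphs[a], ifid)[0]
            ib = footprint(graphs[b], ifid)[0]
            mean = 0.5 * (ref[a][ia] + ref[b][ib])
            ref[a][ia] = mean
            ref[b][ib] = mean
        for uid in graphs:
            assert np.allclose(out.fields[uid], ref[uid], atol=1e-12)

    def test_independent_of_unit_enumeration_order(self, network):
        sg, graphs = network
        model = AssemblyModel(rng=np.random.default_rng(2), identity_init=False)
        gp = _random_prediction(graphs, seed=9)
        out1 = assemble_step(model, sg, graphs, gp)
        sg2 = replace(sg) if hasattr(sg, "__dataclass_fields__") else sg
        from neuriteflow.graph_build import StructureGraph
        sg_shuffled = StructureGraph(units=sg.units,
                                     adjacency=list(reversed(sg.adjacency)),
                                     interfaces=sg.interfaces,
                                     root_unit=sg.root_unit)
        graphs_shuffled = dict(sorted(graphs.items(), reverse=True))
        out2 = assemble_step(model, sg_shuffled, graphs_shuffled, gp)
        for uid in graphs:
            assert np.allclose(out1.fields[uid], out2.fields[uid], atol=1e-14)


class TestAssemblyLoss:
    def test_zero_when_exact_and_consistent(self, network):
        sg, graphs = network
        gp = _agreeing_prediction(sg, graphs)
        assert assembly_loss(gp, gp.copy(), sg, graphs, alpha=10.0) == 0.0

    def test_constant_interface_gap_gives_alpha_delta_squared(self, network):
        """Perfect per-unit field match with a constant two-sided gap δ on
        every interface node (c0 only) costs exactly α·δ²."""
        sg, graphs = network
        delta = 0.37
        gp = _agreeing_prediction(sg, graphs, seed=2)
        for a, b, ifid in sg.adjacency:
            ib = footprint(graphs[b], ifid)[0]
            gp.fields[b][ib, 0] += delta
        truth = gp.copy()   # truth matches each unit's own prediction
        loss = assembly_loss(gp, truth, sg, graphs, alpha=10.0)
        assert loss == pytest.approx(10.0 * delta**2, rel=1e-12)

    def test_alpha_zero_reduces_to_mse(self, network):
        sg, graphs = network
        gp = _random_prediction(graphs, seed=3)
        truth = _random_prediction(graphs, seed=4)
        loss = assembly_loss(gp, truth, sg, graphs, alpha=0.0)
        num, den = 0.0, 0
        for uid in graphs:
            d = gp.fields[uid] - truth.fields[uid]
            num += np.sum(d[:, 0] ** 2 + d[:, 1] ** 2)
            den += len(d)
        assert loss == pytest.approx(num / den, rel=1e-12)

    def test_negative_alpha_rejected(self, network):
        sg, graphs = network
        gp = _random_prediction(graphs)
        with pytest.raises(ValueError, match="alpha"):
            assembly_loss(gp, gp, sg, graphs, alpha=-1.0)

    def test_penalty_zero_iff_sides_agree(self, network):
        sg, graphs = network
        gp = _agreeing_prediction(sg, graphs, seed=6)
        truth = _random_prediction(graphs, seed=7)
        with_pen = assembly_loss(gp, truth, sg, graphs, alpha=10.0)
        without = assembly_loss(gp, truth, sg, graphs, alpha=0.0)
        assert with_pen == pytest.approx(without)


class TestPredictNetwork:
    def test_single_pipe_equals_unit_rollout(self):
        m = generate_morphology(MorphologySpec(n_bifurcations=0, seed=30))
        sg = decompose(m, max_pipe_sections=50)
        assert len(sg.units) == 1
        g = build_unit_graph(sg.units[0])
        params = SimulationParams()
        sim = SimulatorModel("pipe", rng=np.random.default_rng(0))
        preds = predict_network({"pipe": sim}, AssemblyModel(), sg,
                                {0: g}, params, 4)
        init = ConcentrationState.zeros(g.n_nodes)
        # pin the inlet exactly as predict_network does for its initial state
        inlet = g.section_nodes(g.inlet_section)
        init.c0[inlet] = params.c_in
        init.c_plus[inlet] = params.lambda_in * params.c_in
        feats = make_features(g, params, init)
        ref = rollout(sim, g, feats, 4, dt=params.dt)
        for t in range(1, 5):
            assert np.allclose(preds[t].fields[0][:, 0], ref[t].c0)
            assert np.allclose(preds[t].fields[0][:, 1], ref[t].c_plus)

    def test_network_inlet_holds_bc_every_step(self, network):
        sg, graphs = network
        params = SimulationParams()
        sims = {"pipe": SimulatorModel("pipe", rng=np.random.default_rng(0)),
                "bifurcation": SimulatorModel("bifurcation",
                                              rng=np.random.default_rng(1))}
        preds = predict_network(sims, AssemblyModel(), sg, graphs, params, 3)
        root_g = graphs[sg.root_unit]
        rin = root_g.section_nodes(root_g.inlet_section)
        for gp in preds:
            assert np.allclose(gp.fields[sg.root_unit][rin, 0], params.c_in)
            assert np.allclose(gp.fields[sg.root_unit][rin, 1],
                               params.lambda_in * params.c_in)


class TestOtherComponentKinds:
    def test_pipe_pipe_component_used_on_split_pipes(self, monkeypatch):
        m = generate_morphology(MorphologySpec(n_bifurcations=0, seed=40))
        sg = decompose(m, max_pipe_sections=3)
        graphs = {u.unit_id: build_unit_graph(u) for u in sg.units}
        assert len(sg.adjacency) >= 1  # long chain split into several pipes
        model = AssemblyModel(rng=np.random.default_rng(0))
        calls = {"n": 0}
        comp = model.components[("pipe", "pipe")]
        orig = comp.forward
        monkeypatch.setattr(
            comp, "forward",
            lambda x, cache=None: (calls.__setitem__("n", calls["n"] + 1),
                                   orig(x, cache))[1])
        out = assemble_step(model, sg, graphs, _random_prediction(graphs))
        assert calls["n"] == 2 * len(sg.adjacency)
        from neuriteflow.assembly import interface_discrepancy
        assert interface_discrepancy(out, sg, graphs) < 1e-14

    def test_bifurcation_bifurcation_component_dispatch(self):
        """Two bifurcation graphs wired to share an interface id exercise
        the b-b component and still resolve to single-valued interfaces."""
        from neuriteflow.graph_build import StructureGraph
        m = generate_morphology(MorphologySpec(n_bifurcations=1, seed=41))
        sg0 = decompose(m, max_pipe_sections=50)
        bif = next(u for u in sg0.units if u.kind == "bifurcation")
        ga = build_unit_graph(bif)
        gb = build_unit_graph(bif)
        ga.unit_id, gb.unit_id = 0, 1
        # child-0 outlet of unit 0 meets the parent inlet of unit 1
        ifid = 99
        for g, sec in ((ga, 6), (gb, 0)):
            sel = g.section_nodes(sec)
            g.interface_ids[sel] = ifid
        sg = StructureGraph(units=[None, None], adjacency=[(0, 1, ifid)],
                            interfaces={ifid: None}, root_unit=0)
        model = AssemblyModel(rng=np.random.default_rng(1), identity_init=False)
        graphs = {0: ga, 1: gb}
        out = assemble_step(model, sg, graphs, _random_prediction(graphs))
        from neuriteflow.assembly import footprint
        ia = footprint(ga, ifid)[0]
        ib = footprint(gb, ifid)[0]
        assert np.allclose(out.fields[0][ia], out.fields[1][ib])
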