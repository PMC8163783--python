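"""Learned assembly of unit simulators into a network-wide prediction.

Neighbouring units share an interface cross section whose nodes are
predicted twice, once by each unit simulator.  The assembly model is a
message-passing correction: for every (unit, neighbour) pair the interface
values from both sides, together with the current unit's values on the
section adjacent to the interface, are concatenated and passed through an
MLP whose output updates the current unit's interface-adjacent values.
Three components — pipe–pipe, pipe–bifurcation and bifurcation–bifurcation —
are selected by the pair of unit kinds (Fig-style "G_A" components); each is
a three-hidden-layer width-32 ReLU MLP with a linear output, applied as a
residual update so an identity passthrough is available at initialization.

After all pairwise updates (computed Jacobi-style from the incoming
prediction, so the result is independent of unit enumeration order) the two
sides of every interface are averaged to a single value.

Training uses the interface-penalized loss: MSE over the assembled units'
nodes plus α times the mean squared two-sided interface discrepancy
(penalty strength α = 10 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .graph_build import StructureGraph, TemplateGraph
from .gnn import NodeFeatureSet, SimulatorModel, make_features, _predict
from .nn import MLP, MLPGrads
from .solver import SimulationParams, network_velocity

__all__ = [
    "AssemblyModel",
    "GlobalPrediction",
    "assemble_step",
    "assembly_loss",
    "predict_network",
    "interface_discrepancy",
    "footprint",
]

_IF = 17  # nodes per interface section


def _pair_key(kind_a: str, kind_b: str) -> tuple[str, str]:
    return tuple(sorted((kind_a, kind_b)))  # type: ignore[return-value]


class AssemblyModel:
    """The three kind-paired assembly MLPs plus the penalty strength α."""

    IN_DIM = 3 * _IF * 2    # current iface + current adjacent + other iface, 2 fields
    OUT_DIM = 2 * _IF * 2   # update of current iface + adjacent, 2 fields

    def __init__(self, alpha: float = 10.0, hidden: int = 32,
                 rng: np.random.Generator | None = None,
                 identity_init: bool = True):
        if alpha <= 0:
            raise ValueError("penalty strength alpha must be positive")
        if rng is None:
            rng = np.random.default_rng(0)
        self.alpha = alpha
        self.components: dict[tuple[str, str], MLP] = {}
        for key in (("pipe", "pipe"), ("bifurcation", "pipe"),
                    ("bifurcation", "bifurcation")):
            self.components[key] = MLP(
                [self.IN_DIM, hidden, hidden, hidden, self.OUT_DIM], rng,
                zero_output=identity_init)

    def component(self, kind_a: str, kind_b: str) -> MLP:
        return self.components[_pair_key(kind_a, kind_b)]

    def params(self):
        out = []
        for key in sorted(self.components):
            m = self.components[key]
            out += m.W + m.b
        return out

    def grads(self) -> dict:
        return {key: MLPGrads(m) for key, m in self.components.items()}

    def state_dict(self) -> dict:
        return {"alpha": self.alpha,
                "components": {"|".join(k): m.state_dict()
                               for k, m in self.components.items()}}

    @classmethod
    def from_state(cls, state: dict) -> "AssemblyModel":
        m = cls.__new__(cls)
        m.alpha = state["alpha"]
        m.components = {tuple(k.split("|")): MLP.from_state(s)  # type: ignore[misc]
                        for k, s in state["components"].items()}
        return m

    def copy(self) -> "AssemblyModel":
        return AssemblyModel.from_state(self.state_dict())


@dataclass
class GlobalPrediction:
    """Per-unit nodal fields (N_u, 2) at one time step."""

    fields: dict[int, np.ndarray]
    time: float = 0.0

    def copy(self) -> "GlobalPrediction":
        return GlobalPrediction({k: v.copy() for k, v in self.fields.items()},
                                self.time)


def footprint(g: TemplateGraph, iface_id: int):
    """(interface nodes, adjacent-section nodes) for one unit and interface,
    both in template order (17 each)."""
    iface = g.interface_nodes(iface_id)
    iface = iface[g.node_template_index[iface] < _IF]
    s = int(g.node_section[iface[0]])
    if s == g.inlet_section:
        down = np.flatnonzero(g.section_upstream == s)
        adj = int(down[0])
    else:
        adj = int(g.section_upstream[s])
    sel = g.section_nodes(adj)
    sel = sel[g.node_template_index[sel] < _IF]
    return iface, sel[np.argsort(g.node_template_index[sel])]


def _pack(cur_if, cur_adj, oth_if) -> np.ndarray:
    return np.concatenate([cur_if[:, 0], cur_if[:, 1],
                           cur_adj[:, 0], cur_adj[:, 1],
                           oth_if[:, 0], oth_if[:, 1]])


def _unpack(vec: np.ndarray):
    return (np.column_stack([vec[0:_IF], vec[_IF:2 * _IF]]),
            np.column_stack([vec[2 * _IF:3 * _IF], vec[3 * _IF:4 * _IF]]))


def assemble_step(model: AssemblyModel, sg: StructureGraph,
                  graphs: dict[int, TemplateGraph],
                  intermediate: GlobalPrediction,
                  c_scale: float = 1.0,
                  gap_out: list | None = None) -> GlobalPrediction:
    """One assembly pass.

    All pairwise updates are computed from the incoming prediction and only
    then applied (so the output does not depend on the order units are
    enumerated in); nodes touched by several invocations receive the mean
    update, and finally both sides of each interface are averaged so every
    interface value is single-valued.
    """
    for uid in graphs:
        if uid not in intermediate.fields:
            raise ValueError(f"no prediction for unit {uid}")
    acc = {uid: np.zeros_like(intermediate.fields[uid]) for uid in graphs}
    cnt = {uid: np.zeros(len(intermediate.fields[uid])) for uid in graphs}

    for a, b, ifid in sorted(sg.adjacency, key=lambda t: t[2]):
        for cur, oth in ((a, b), (b, a)):
            gc, go = graphs[cur], graphs[oth]
            if_c, adj_c = footprint(gc, ifid)
            if_o, _ = footprint(go, ifid)
            x = _pack(intermediate.fields[cur][if_c] / c_scale,
                      intermediate.fields[cur][adj_c] / c_scale,
                      intermediate.fields[oth][if_o] / c_scale)
            delta = model.component(gc.kind, go.kind).forward(x[None, :])[0]
            d_if, d_adj = _unpack(delta * c_scale)
            acc[cur][if_c] += intermediate.fields[cur][if_c] + d_if
            acc[cur][adj_c] += intermediate.fields[cur][adj_c] + d_adj
            cnt[cur][if_c] += 1
            cnt[cur][adj_c] += 1

    out = intermediate.copy()
    for uid in graphs:
        touched = cnt[uid] > 0
        out.fields[uid][touched] = acc[uid][touched] / cnt[uid][touched, None]

    if gap_out is not None:
        # two-sided interface gap after the component updates, before the
        # averaging that enforces single-valuedness
        gap_out.append(interface_discrepancy(out, sg, graphs))

    # resolve interfaces to a single value
    for a, b, ifid in sorted(sg.adjacency, key=lambda t: t[2]):
        ia = footprint(graphs[a], ifid)[0]
        ib = footprint(graphs[b], ifid)[0]
        mean = 0.5 * (out.fields[a][ia] + out.fields[b][ib])
        out.fields[a][ia] = mean
        out.fields[b][ib] = mean
    return out


def assembly_loss(pred: GlobalPrediction, truth: GlobalPrediction,
                  sg: StructureGraph, graphs: dict[int, TemplateGraph],
                  alpha: float = 10.0,
                  units: tuple[int, int] | None = None,
                  iface_id: int | None = None) -> float:
    """Interface-penalized MSE.

    MSE of both fields over the assembled units' nodes plus α times the mean
    squared discrepancy between the two sides' interface predictions.  By
    default all units/interfaces of the structure graph contribute; a single
    (unit pair, interface) can be selected for pairwise training.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    pairs = sorted(sg.adjacency, key=lambda t: t[2])
    if iface_id is not None:
        pairs = [p for p in pairs if p[2] == iface_id]
    uids = sorted(units if units is not None else graphs.keys())

    n = 0
    sq = 0.0
    for uid in uids:
        d = pred.fields[uid] - truth.fields[uid]
        sq += float(np.sum(d[:, 0] ** 2 + d[:, 1] ** 2))
        n += len(d)
    loss = sq / max(n, 1)

    m = 0
    pen = 0.0
    for a, b, ifid in pairs:
        if units is not None and {a, b} != set(units):
            continue
        ia = footprint(graphs[a], ifid)[0]
        ib = footprint(graphs[b], ifid)[0]
        gap = pred.fields[a][ia] - pred.fields[b][ib]
        pen += float(np.sum(gap[:, 0] ** 2 + gap[:, 1] ** 2))
        m += len(ia)
    if m:
        loss += alpha * pen / m
    return loss


def interface_discrepancy(pred: GlobalPrediction, sg: StructureGraph,
                          graphs: dict[int, TemplateGraph]) -> float:
    """Mean absolute two-sided gap over all interface nodes and fields."""
    tot, m = 0.0, 0
    for a, b, ifid in sg.adjacency:
        ia = footprint(graphs[a], ifid)[0]
        ib = footprint(graphs[b], ifid)[0]
        tot += float(np.sum(np.abs(pred.fields[a][ia] - pred.fields[b][ib])))
        m += ia.size * 2
    return tot / max(m, 1)


def predict_network(simulators: dict[str, SimulatorModel],
                    assembly_model: AssemblyModel | None,
                    sg: StructureGraph, graphs: dict[int, TemplateGraph],
                    params: SimulationParams, n_steps: int,
                    n_passes: int = 1,
                    gap_log: list | None = None) -> list[GlobalPrediction]:
    """Autoregressive network rollout.

    Each time step: every unit simulator advances its local state (interior
    units take their upstream neighbour's current interface values as their
    inlet Dirichlet data; the root unit takes the network boundary
    condition), then the assembly model reconciles the interfaces, and the
    reconciled fields feed the next step.  Inlet speeds per unit come from
    network flux propagation.
    """
    c_scale = params.c_in or 1.0
    u_in = network_velocity(sg, graphs, params)
    upstream_of: dict[int, tuple[int, int]] = {}
    for a, b, ifid in sg.adjacency:
        # the unit whose *inlet* carries this interface is downstream
        for cur, oth in ((a, b), (b, a)):
            g = graphs[cur]
            inlet_if = {v for v in g.interface_ids[g.section_nodes(g.inlet_section)]
                        if v is not None}
            if ifid in inlet_if:
                upstream_of[cur] = (oth, ifid)

    unit_params = {uid: replace(params, u_i=u_in[uid]) for uid in graphs}
    state = GlobalPrediction({uid: np.zeros((graphs[uid].n_nodes, 2))
                              for uid in graphs}, 0.0)
    # impose the network inlet on the initial state
    root_g = graphs[sg.root_unit]
    rin = root_g.section_nodes(root_g.inlet_section)
    state.fields[sg.root_unit][rin, 0] = params.c_in or 0.0
    state.fields[sg.root_unit][rin, 1] = params.lambda_in * (params.c_in or 0.0)

    out = [state.copy()]
    for step in range(n_steps):
        nxt = {}
        for uid in sorted(graphs):
            g = graphs[uid]
            if uid == sg.root_unit:
                inlet_vals = None  # scalar BC from params
            else:
                up, ifid = upstream_of[uid]
                src = footprint(graphs[up], ifid)[0]
                vals = state.fields[up][src] / c_scale
                inlet_vals = (vals[:, 0], vals[:, 1])
            from .solver import ConcentrationState
            st = ConcentrationState(state.fields[uid][:, 0], state.fields[uid][:, 1])
            feats = make_features(g, unit_params[uid], st, c_scale=c_scale,
                                  inlet_values=inlet_vals)
            ub = np.array([1.05, 1.05 * params.lambda_in]) * c_scale
            pred = np.clip(_predict(simulators[g.kind], g, feats) * c_scale, 0.0, ub)
            nxt[uid] = pred
        gp = GlobalPrediction(nxt, (step + 1) * params.dt)
        if assembly_model is not None and sg.adjacency:
            for _ in range(n_passes):
                gp = assemble_step(assembly_model, sg, graphs, gp,
                                   c_scale=c_scale, gap_out=gap_log)
        # keep the network inlet pinned after assembly
        gp.fields[sg.root_unit][rin, 0] = params.c_in or 0.0
        gp.fields[sg.root_unit][rin, 1] = params.lambda_in * (params.c_in or 0.0)
        state = gp
        out.append(state.copy())
    return out
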