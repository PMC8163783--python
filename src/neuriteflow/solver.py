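"""Reference solver for the unidirectional motor-assisted transport model.

The model couples a freely diffusing species ``c0`` with a motor-bound,
advected species ``c+`` (concentrations in mol/μm³):

    dc0/dt = D ∇²c0 − k₊ c0 + k₊' c₊
    dc₊/dt = −u₊·∇c₊ + k₊ c0 − k₊' c₊

with Dirichlet values ``c0 = c, c₊ = λ c`` at the incoming end.  The filament
system is assumed unipolar (unidirectional transport), which drops the
retrograde species; a bidirectional mode that evolves ``c−`` as well is kept
behind a flag.  The velocity field is the analytic Poiseuille profile
``u(r) = u_sec (1 − (r/R)²)`` along the local centerline tangent, with the
section speed ``u_sec`` set by volumetric flux conservation: flux is constant
along a pipe and splits between the two daughters of a bifurcation in
proportion to their cross-section areas.

Spatial operators are the simplest consistent ones on a template graph:
diffusion through a symmetric graph Laplacian with edge weights ``1/ℓ²``
(exact second difference on a uniform chain, mass-conserving by symmetry)
and first-order upwinding of the advective term using the velocity component
along each edge.  Time stepping is explicit Euler; the recording step
(default 0.1 s) is internally subdivided to satisfy stability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .graph_build import TemplateGraph, StructureGraph, build_unit_graph

__all__ = [
    "save_trajectory_hdf5",
    "load_trajectory_hdf5",
    "steady_state_to_csv",
    "SimulationParams",
    "ConcentrationState",
    "VelocityField",
    "StabilityError",
    "compute_velocity",
    "build_operators",
    "solve_transport",
    "run_to_steady_state",
    "SteadyStateResult",
    "merge_network",
    "MergedNetwork",
    "network_velocity",
    "solve_network",
]


class StabilityError(RuntimeError):
    """The explicit integration diverged; reduce dt."""


@dataclass
class SimulationParams:
    """Physical and numerical parameters of the transport model.

    Defaults are the study conditions: D = 1.0 μm²/s, k± = 1.0 /s,
    k'± = 0.5 /s, u_i = 0.1 μm/s, dt = 0.1 s, and degree of loading
    λ = k₊/k₊' = 2 so the inlet is in attachment/detachment equilibrium.
    """

    D: float = 1.0
    k_plus: float = 1.0
    k_minus: float = 1.0
    kp_plus: float = 0.5
    kp_minus: float = 0.5
    u_i: float = 0.1
    lambda_in: float = 2.0
    lambda_out: float = 2.0
    c_in: float | None = 1.0
    c_out: float | None = None
    dt: float = 0.1
    unidirectional: bool = True

    def __post_init__(self):
        if self.D < 0 or min(self.k_plus, self.k_minus, self.kp_plus, self.kp_minus) < 0:
            raise ValueError("D and rate constants must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class ConcentrationState:
    """Per-node concentrations (mol/μm³) at one time."""

    c0: np.ndarray
    c_plus: np.ndarray
    time: float = 0.0
    c_minus: np.ndarray | None = None

    def copy(self) -> "ConcentrationState":
        return ConcentrationState(self.c0.copy(), self.c_plus.copy(), self.time,
                                  None if self.c_minus is None else self.c_minus.copy())

    @classmethod
    def zeros(cls, n: int, bidirectional: bool = False) -> "ConcentrationState":
        return cls(np.zeros(n), np.zeros(n), 0.0,
                   np.zeros(n) if bidirectional else None)


@dataclass
class VelocityField:
    """Anterograde velocity u₊ per node, plus per-section diagnostics."""

    vectors: np.ndarray   # (N, 3) μm/s
    u_sec: np.ndarray     # (S,) centerline peak speed per section
    flux: np.ndarray      # (S,) volumetric flux Q = A·u_sec/2


def compute_velocity(g: TemplateGraph, params: SimulationParams,
                     u_inlet: float | None = None) -> VelocityField:
    """Parabolic-profile velocity on a template graph.

    ``u_inlet`` overrides ``params.u_i`` as the inlet-section centerline
    speed (used when a unit sits inside a network and inherits its flux).
    At each node, speed = u_sec (1 − (r/R)²) directed along the section
    tangent; u_sec follows from flux conservation with area-proportional
    splitting at the bifurcation branch point.
    """
    if not np.any((g.roles == "inlet") | (g.node_section == g.inlet_section)):
        raise ValueError("graph has no inlet section")
    S = g.n_sections
    u_sec = np.zeros(S)
    Q = np.zeros(S)
    area = np.pi * g.section_radii ** 2
    downstream: dict[int, list[int]] = {}
    for s in range(S):
        up = int(g.section_upstream[s])
        if up >= 0:
            downstream.setdefault(up, []).append(s)

    u0 = params.u_i if u_inlet is None else u_inlet
    # topological pass: the inlet section has upstream -1 and section ids
    # increase downstream within each branch
    for s in range(S):
        if g.section_upstream[s] == -1:
            u_sec[s] = u0
            Q[s] = area[s] * u0 / 2.0
    for s in range(S):
        kids = downstream.get(s, [])
        if not kids:
            continue
        if len(kids) == 1:
            Q[kids[0]] = Q[s]
        else:
            a = area[kids]
            for c, frac in zip(kids, a / a.sum()):
                Q[c] = Q[s] * frac
        for c in kids:
            u_sec[c] = 2.0 * Q[c] / area[c]

    speed = u_sec[g.node_section] * (1.0 - g.rfrac ** 2)
    vectors = speed[:, None] * g.section_tangents[g.node_section]
    return VelocityField(vectors=vectors, u_sec=u_sec, flux=Q)


# ---------------------------------------------------------------------------
# discrete operators
# ---------------------------------------------------------------------------

@dataclass
class Operators:
    """Sparse spatial operators and boundary bookkeeping for one graph."""

    lap: sp.csr_matrix        # (L c)_i = Σ_j (c_j - c_i)/ℓ², symmetric
    adv: sp.csr_matrix        # (A c)_i ≈ -(u·∇c)_i, first-order upwind
    inlet_nodes: np.ndarray
    outlet_dst: np.ndarray    # outlet nodes (zero-gradient copy targets)
    outlet_src: np.ndarray    # matching interior source nodes
    min_edge: float
    interior: np.ndarray      # bool mask: nodes where the PDE rows apply
    adv_minus: sp.csr_matrix | None = None  # upwind operator for -u (c−)


def _laplacian(positions: np.ndarray, edges: np.ndarray, n: int) -> sp.csr_matrix:
    i, j = edges[:, 0], edges[:, 1]
    ell = np.linalg.norm(positions[i] - positions[j], axis=1)
    if np.any(ell <= 0):
        raise ValueError("coincident edge endpoints")
    w = 1.0 / ell ** 2
    rows = np.concatenate([i, j, i, j])
    cols = np.concatenate([j, i, i, j])
    vals = np.concatenate([w, w, -w, -w])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _upwind(positions: np.ndarray, edges: np.ndarray, vectors: np.ndarray,
            n: int) -> sp.csr_matrix:
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    d = positions[j] - positions[i]
    ell = np.linalg.norm(d, axis=1)
    s = np.einsum("ij,ij->i", vectors[i], d) / ell
    up = s < 0  # flow arrives from j
    a = -s[up] / ell[up]
    rows = np.concatenate([i[up], i[up]])
    cols = np.concatenate([j[up], i[up]])
    vals = np.concatenate([a, -a])
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def build_operators(g: TemplateGraph, v: VelocityField,
                    params: SimulationParams) -> Operators:
    """Assemble Laplacian / upwind operators and boundary index maps."""
    n = g.n_nodes
    lap = _laplacian(g.positions, g.edges, n)
    adv = _upwind(g.positions, g.edges, v.vectors, n)
    inlet = g.section_nodes(g.inlet_section)
    dst, src = [], []
    for s in g.outlet_sections:
        up = int(g.section_upstream[s])
        sel = g.section_nodes(s)
        sel = sel[g.node_template_index[sel] < 17]
        for node in sel:
            t = g.node_template_index[node]
            cand = g.section_nodes(up)
            match = cand[g.node_template_index[cand] == t]
            dst.append(node)
            src.append(int(match[0]))
    ell = np.linalg.norm(g.positions[g.edges[:, 0]] - g.positions[g.edges[:, 1]], axis=1)
    interior = np.ones(n, dtype=bool)
    interior[inlet] = False
    interior[np.asarray(dst, dtype=int)] = False
    adv_minus = None
    if not params.unidirectional:
        adv_minus = _upwind(g.positions, g.edges, -v.vectors, n)
    return Operators(lap=lap, adv=adv, inlet_nodes=inlet,
                     outlet_dst=np.asarray(dst, dtype=int),
                     outlet_src=np.asarray(src, dtype=int),
                     min_edge=float(ell.min()), interior=interior,
                     adv_minus=adv_minus)


def _stable_dt(ops: Operators, params: SimulationParams) -> float:
    h = ops.min_edge
    bound = np.inf
    if params.D > 0:
        bound = min(bound, 0.4 * h * h / (2 * params.D))
    # operator-based bound: explicit Euler needs dt * (total outflow rate) < 1
    rate = params.D * float(np.abs(ops.lap).sum(axis=1).max()) if params.D > 0 else 0.0
    rate += float(np.abs(ops.adv).sum(axis=1).max()) if ops.adv.nnz else 0.0
    rate += max(params.k_plus, params.kp_plus)
    if rate > 0:
        bound = min(bound, 0.9 / rate)
    return bound


def _apply_bcs(state: ConcentrationState, ops: Operators, params: SimulationParams,
               inlet_values=None) -> None:
    if inlet_values is not None:
        c0_in, cp_in = inlet_values
        state.c0[ops.inlet_nodes] = c0_in
        state.c_plus[ops.inlet_nodes] = cp_in
    elif params.c_in is not None:
        state.c0[ops.inlet_nodes] = params.c_in
        state.c_plus[ops.inlet_nodes] = params.lambda_in * params.c_in
    if len(ops.outlet_dst):
        if params.c_out is not None:
            state.c0[ops.outlet_dst] = params.c_out
            if state.c_minus is not None:
                state.c_minus[ops.outlet_dst] = params.lambda_out * params.c_out
        else:
            state.c0[ops.outlet_dst] = state.c0[ops.outlet_src]
            state.c_plus[ops.outlet_dst] = state.c_plus[ops.outlet_src]
            if state.c_minus is not None:
                state.c_minus[ops.outlet_dst] = state.c_minus[ops.outlet_src]


def _rhs(state: ConcentrationState, ops: Operators, params: SimulationParams):
    c0, cp = state.c0, state.c_plus
    d0 = params.D * (ops.lap @ c0) - params.k_plus * c0 + params.kp_plus * cp
    dp = ops.adv @ cp + params.k_plus * c0 - params.kp_plus * cp
    dm = None
    if not params.unidirectional and state.c_minus is not None:
        cm = state.c_minus
        d0 = d0 - params.k_minus * c0 + params.kp_minus * cm
        # retrograde species moves against the anterograde field; its own
        # upwind operator is built from the mirrored velocity
        adv_m = ops.adv_minus if ops.adv_minus is not None else ops.adv.T * 0
        dm = adv_m @ cm + params.k_minus * c0 - params.kp_minus * cm
    return d0, dp, dm


def solve_transport(g: TemplateGraph, params: SimulationParams, v: VelocityField,
                    init: ConcentrationState, n_steps: int,
                    closed: bool = False, inlet_values=None,
                    ops: Operators | None = None) -> list[ConcentrationState]:
    """Integrate the transport model, recording a state every ``params.dt``.

    Explicit Euler with internal substepping to satisfy stability; Dirichlet
    inlet values (``c_in, λ c_in`` or the explicit ``inlet_values`` pair) are
    re-imposed every substep, outlets are zero-gradient unless ``c_out`` is
    given.  ``closed=True`` disables all boundary handling (no-flux
    everywhere), which is useful for conservation checks.

    Returns ``n_steps + 1`` states including the initial one.  Raises
    :class:`StabilityError` if the solution blows up.
    """
    if ops is None:
        ops = build_operators(g, v, params)
    dt_stable = _stable_dt(ops, params)
    n_sub = max(1, int(np.ceil(params.dt / dt_stable)))
    h = params.dt / n_sub

    state = init.copy()
    if not closed:
        _apply_bcs(state, ops, params, inlet_values)
    ref = max(float(np.max(np.abs(state.c0), initial=0.0)),
              float(np.max(np.abs(state.c_plus), initial=0.0)),
              params.c_in or 0.0, 1e-12)
    traj = [state.copy()]
    for step in range(n_steps):
        for _ in range(n_sub):
            d0, dp, dm = _rhs(state, ops, params)
            state.c0 += h * d0
            state.c_plus += h * dp
            if dm is not None:
                state.c_minus += h * dm
            if not closed:
                _apply_bcs(state, ops, params, inlet_values)
        state.time += params.dt
        m = max(float(np.max(np.abs(state.c0))), float(np.max(np.abs(state.c_plus))))
        if not np.isfinite(m) or m > 1e6 * ref:
            raise StabilityError(
                f"solution diverged at t={state.time:.3f}s; reduce dt "
                f"(stable substep ≈ {dt_stable:.2e}s)")
        traj.append(state.copy())
    return traj


@dataclass
class SteadyStateResult:
    trajectory: list[ConcentrationState]
    steady_time: float
    steady: bool


def run_to_steady_state(g: TemplateGraph, params: SimulationParams, v: VelocityField,
                        init: ConcentrationState, tol: float = 1e-4,
                        max_time: float = 1000.0,
                        ops: Operators | None = None) -> SteadyStateResult:
    """Integrate until the max-norm relative change per second drops below
    ``tol`` (checked every recording step) or ``max_time`` is reached."""
    if ops is None:
        ops = build_operators(g, v, params)
    traj = [init.copy()]
    state = traj[0]
    t = 0.0
    while t < max_time - 1e-12:
        nxt = solve_transport(g, params, v, state, 1, ops=ops)[-1]
        t += params.dt
        scale = max(float(np.max(np.abs(nxt.c0))), float(np.max(np.abs(nxt.c_plus))), 1e-30)
        change = max(float(np.max(np.abs(nxt.c0 - state.c0))),
                     float(np.max(np.abs(nxt.c_plus - state.c_plus))))
        rel_per_s = change / (params.dt * scale)
        traj.append(nxt)
        state = nxt
        if rel_per_s < tol:
            return SteadyStateResult(traj, steady_time=t, steady=True)
    return SteadyStateResult(traj, steady_time=t, steady=False)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------

def save_trajectory_hdf5(path, traj: list[ConcentrationState],
                         unit_id: int = 0, mode: str = "a") -> None:
    """Store a trajectory under ``/unit_<id>/t_<k>/{c0,c_plus}`` with the
    time stamp as a group attribute."""
    import h5py

    with h5py.File(path, mode) as f:
        grp = f.require_group(f"unit_{unit_id}")
        for k, st in enumerate(traj):
            g = grp.create_group(f"t_{k}")
            g.attrs["time"] = st.time
            g.create_dataset("c0", data=st.c0)
            g.create_dataset("c_plus", data=st.c_plus)
            if st.c_minus is not None:
                g.create_dataset("c_minus", data=st.c_minus)


def load_trajectory_hdf5(path, unit_id: int = 0) -> list[ConcentrationState]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        grp = f[f"unit_{unit_id}"]
        for name in sorted(grp, key=lambda s: int(s.split("_")[1])):
            g = grp[name]
            out.append(ConcentrationState(
                c0=g["c0"][()], c_plus=g["c_plus"][()],
                time=float(g.attrs["time"]),
                c_minus=g["c_minus"][()] if "c_minus" in g else None))
    return out


def steady_state_to_csv(path, g: TemplateGraph, state: ConcentrationState) -> None:
    """Per-node steady-state export: position, section, radius, fields."""
    import pandas as pd

    pd.DataFrame({
        "node": np.arange(g.n_nodes),
        "x": g.positions[:, 0], "y": g.positions[:, 1], "z": g.positions[:, 2],
        "section": g.node_section, "radius": g.node_radii,
        "c0": state.c0, "c_plus": state.c_plus,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# whole-network ground truth
# ---------------------------------------------------------------------------

@dataclass
class MergedNetwork:
    """All unit graphs glued at their interfaces into one simulation graph."""

    graph: TemplateGraph
    node_maps: dict[int, np.ndarray]   # unit_id -> (n_local,) global indices
    unit_u_inlet: dict[int, float]     # propagated inlet centerline speed


def network_velocity(sg: StructureGraph, graphs: dict[int, TemplateGraph],
                     params: SimulationParams) -> dict[int, float]:
    """Propagate the inlet centerline speed through the unit graph so every
    unit sees the flux arriving from upstream (area-weighted splitting)."""
    u_in: dict[int, float] = {sg.root_unit: params.u_i}
    seen = {sg.root_unit}
    stack = [sg.root_unit]
    while stack:
        uid = stack.pop()
        g = graphs[uid]
        vf = compute_velocity(g, params, u_inlet=u_in[uid])
        for s_out in g.outlet_sections:
            ifid = None
            sel = g.section_nodes(s_out)
            vals = {v for v in g.interface_ids[sel] if v is not None}
            if vals:
                ifid = vals.pop()
            if ifid is None:
                continue
            nb = [b for b, i in sg.neighbors(uid) if i == ifid and b not in seen]
            for b in nb:
                u_in[b] = float(vf.u_sec[s_out])
                seen.add(b)
                stack.append(b)
    return u_in


def merge_network(sg: StructureGraph, graphs: dict[int, TemplateGraph],
                  tol: float = 1e-6) -> MergedNetwork:
    """Glue unit template graphs into one global graph, identifying the
    duplicated interface nodes (positions must coincide within ``tol``)."""
    uids = sorted(graphs)
    offsets = {}
    total = 0
    for uid in uids:
        offsets[uid] = total
        total += graphs[uid].n_nodes
    glob = {uid: np.arange(graphs[uid].n_nodes) + offsets[uid] for uid in uids}

    # identify interface duplicates: keep the lower-unit-id copy
    for a, b, ifid in sorted(sg.adjacency, key=lambda t: t[2]):
        ga, gb = graphs[a], graphs[b]
        na, nb_ = ga.interface_nodes(ifid), gb.interface_nodes(ifid)
        if len(na) != len(nb_):
            raise ValueError(f"interface {ifid} node-count mismatch")
        if not np.allclose(ga.positions[na], gb.positions[nb_], atol=tol):
            raise ValueError(f"interface {ifid} node positions do not coincide")
        glob[b][nb_] = glob[a][na]

    # compress to consecutive indices
    used = np.unique(np.concatenate([glob[uid] for uid in uids]))
    remap = -np.ones(total, dtype=np.int64)
    remap[used] = np.arange(len(used))
    for uid in uids:
        glob[uid] = remap[glob[uid]]
    n = len(used)

    positions = np.zeros((n, 3))
    rfrac = np.zeros(n)
    node_radii = np.zeros(n)
    roles = np.array(["interior"] * n, dtype=object)
    tmpl = np.zeros(n, dtype=np.int64)
    for uid in uids:
        g = graphs[uid]
        positions[glob[uid]] = g.positions
        rfrac[glob[uid]] = g.rfrac
        node_radii[glob[uid]] = g.node_radii
        tmpl[glob[uid]] = g.node_template_index
        for k in range(g.n_nodes):
            if g.roles[k] in ("inlet", "outlet"):
                roles[glob[uid][k]] = g.roles[k]

    edges = np.unique(np.sort(np.concatenate(
        [glob[uid][graphs[uid].edges] for uid in uids]), axis=1), axis=0)

    # sections: concatenate unit sections; interface sections deduplicate via
    # upstream copy bookkeeping not needed globally — keep unit-local sections
    # and give the merged graph flat per-node section metadata instead.
    merged = TemplateGraph(
        kind="network", unit_id=-1, positions=positions,
        node_section=np.zeros(n, dtype=np.int64), node_template_index=tmpl,
        rfrac=rfrac, node_radii=node_radii, edges=edges,
        roles=roles.astype(str),
        interface_ids=np.array([None] * n, dtype=object),
        section_centers=np.zeros((1, 3)), section_tangents=np.zeros((1, 3)),
        section_radii=np.zeros(1), section_upstream=np.array([-1]),
        inlet_section=0, outlet_sections=[],
    )
    return MergedNetwork(graph=merged, node_maps=glob, unit_u_inlet={})


def solve_network(sg: StructureGraph, graphs: dict[int, TemplateGraph],
                  params: SimulationParams, n_steps: int,
                  init: ConcentrationState | None = None):
    """Reference solve on the glued network graph.

    Builds the merged graph, propagates flux to get a global velocity field,
    and integrates with Dirichlet values at the network inlet and
    zero-gradient outlets at the tips.  Returns ``(trajectory, merged)``.
    """
    merged = merge_network(sg, graphs)
    u_in = network_velocity(sg, graphs, params)
    merged.unit_u_inlet = u_in

    n = merged.graph.n_nodes
    vectors = np.zeros((n, 3))
    for uid in sorted(graphs):
        vf = compute_velocity(graphs[uid], params, u_inlet=u_in[uid])
        vectors[merged.node_maps[uid]] = vf.vectors
    vel = VelocityField(vectors=vectors, u_sec=np.zeros(1), flux=np.zeros(1))

    # boundary bookkeeping on the merged graph
    inlet_nodes = []
    dst, src = [], []
    root_g = graphs[sg.root_unit]
    inlet_nodes = merged.node_maps[sg.root_unit][root_g.section_nodes(root_g.inlet_section)]
    for uid in sorted(graphs):
        g = graphs[uid]
        for s in g.outlet_sections:
            sel = g.section_nodes(s)
            if g.roles[sel[0]] != "outlet":
                continue
            up = int(g.section_upstream[s])
            sel17 = sel[g.node_template_index[sel] < 17]
            cand = g.section_nodes(up)
            for node in sel17:
                t = g.node_template_index[node]
                match = cand[g.node_template_index[cand] == t][0]
                dst.append(int(merged.node_maps[uid][node]))
                src.append(int(merged.node_maps[uid][match]))

    lap = _laplacian(merged.graph.positions, merged.graph.edges, n)
    adv = _upwind(merged.graph.positions, merged.graph.edges, vectors, n)
    ell = np.linalg.norm(merged.graph.positions[merged.graph.edges[:, 0]]
                         - merged.graph.positions[merged.graph.edges[:, 1]], axis=1)
    interior = np.ones(n, dtype=bool)
    interior[inlet_nodes] = False
    interior[np.asarray(dst, dtype=int)] = False
    ops = Operators(lap=lap, adv=adv, inlet_nodes=np.asarray(inlet_nodes),
                    outlet_dst=np.asarray(dst, dtype=int),
                    outlet_src=np.asarray(src, dtype=int),
                    min_edge=float(ell.min()), interior=interior)
    if init is None:
        init = ConcentrationState.zeros(n)
    traj = solve_transport(merged.graph, params, vel, init, n_steps, ops=ops)
    return traj, merged
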