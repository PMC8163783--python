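"""Graph-network simulators for pipe and bifurcation units.

Architecture (encode – process – decode):

* analytic edge function: for an edge between nodes i, j with positions p
  and a nodal scalar c, the edge attributes are
  ``[(c_j − c_i)/‖p_j − p_i‖, ‖p_j − p_i‖]`` — a finite-difference
  concentration gradient and the edge length;
* a linear encoder lifts the nodal features (coordinates, parameter vector,
  current concentrations) to a 32-dimensional embedding;
* L graph-network blocks: each node reduces its incident edge attributes to
  permutation-invariant statistics (mean gradient, summed second-difference,
  upwind-weighted gradient, mean length, degree), concatenates them with its
  embedding and applies a two-hidden-layer width-32 ReLU MLP;
* an MLP decoder (three hidden layers, width 32, linear output) maps the
  final embedding to the two concentrations at the next time step, after
  which the inlet Dirichlet values are re-imposed.

The physics-informed training loss adds the squared residuals of the two
governing transport equations — evaluated with the reference solver's own
discrete Laplacian/upwind operators — to the usual MSE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph_build import TemplateGraph
from .nn import MLP, MLPGrads
from .solver import (ConcentrationState, Operators, SimulationParams,
                     VelocityField, build_operators)

__all__ = [
    "GNBlockConfig",
    "NodeFeatureSet",
    "SimulatorModel",
    "edge_features",
    "aggregate_edge_features",
    "gn_block_forward",
    "simulator_step",
    "rollout",
    "simulator_loss",
    "make_features",
]

N_PARAM_FEATURES = 8  # D, k+, k'+, u_i, c_in, r/R, section radius, |u| at node
N_AGG_FEATURES = 8    # per field: mean e1, sum e1/e2, upwind sum; plus mean e2, degree
HIDDEN = 32


@dataclass
class GNBlockConfig:
    """GN-block hyperparameters: L message-passing steps, node-MLP width."""

    n_steps: int = 3
    hidden: int = HIDDEN

    def __post_init__(self):
        if self.n_steps < 1:
            raise ValueError("need at least one GN step")


def edge_features(pos_i, pos_j, c_i, c_j) -> np.ndarray:
    """Analytic edge attributes ``[(c_j − c_i)/‖Δp‖, ‖Δp‖]``."""
    d = np.asarray(pos_j, dtype=float) - np.asarray(pos_i, dtype=float)
    ell = float(np.linalg.norm(d))
    if ell == 0.0:
        raise ValueError("coincident edge endpoints")
    return np.array([(c_j - c_i) / ell, ell])


def aggregate_edge_features(positions: np.ndarray, c: np.ndarray,
                            edges: np.ndarray, n: int | None = None,
                            dirs: np.ndarray | None = None) -> np.ndarray:
    """Permutation-invariant per-node reduction of the analytic edge
    attributes ``e = [(c_j − c_i)/ℓ, ℓ]``.

    For each field the reducer emits the mean gradient ``mean(e₁)``, the
    summed second-difference ingredient ``sum(e₁/e₂) = Σ Δc/ℓ²`` (the exact
    row of the solver's graph Laplacian) and — when per-node flow directions
    ``dirs`` are given — an upwind-weighted gradient
    ``Σ (Δc/ℓ)·max(0, −û·d̂)`` matching the solver's upwind stencil; plus the
    mean edge length and the node degree.  ``c`` may be (N,) or (N, F);
    output shape is (N, 2 + 3F) for given ``dirs`` and (N, 2 + 2F) padded
    with zero upwind columns otherwise.  Isolated nodes get zeros.
    """
    if n is None:
        n = len(positions)
    c = np.atleast_2d(np.asarray(c, dtype=float).T).T  # (N, F)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    d = positions[j] - positions[i]
    ell = np.linalg.norm(d, axis=1)
    deg = np.bincount(i, minlength=n).astype(float)
    iso = deg == 0
    deg_div = deg.copy()
    if np.any(iso):
        warnings.warn("isolated node(s): aggregated edge features set to zero")
        deg_div[iso] = 1.0
    if dirs is not None:
        upw_w = np.maximum(0.0, -np.einsum("ij,ij->i", dirs[i], d / ell[:, None]))
    else:
        upw_w = np.zeros_like(ell)
    cols = []
    for f in range(c.shape[1]):
        grad = (c[j, f] - c[i, f]) / ell
        cols.append(np.bincount(i, weights=grad, minlength=n) / deg_div)
        # scaled as the explicit-Euler diffusion increment at the reference
        # parameters (dt·D = 0.1 μm²), keeping the statistic O(Δc)
        cols.append(0.1 * np.bincount(i, weights=grad / ell, minlength=n))
        cols.append(np.bincount(i, weights=grad * upw_w, minlength=n))
    cols.append(np.bincount(i, weights=ell, minlength=n) / deg_div)
    cols.append(deg)
    return np.column_stack(cols)


@dataclass
class NodeFeatureSet:
    """Per-node inputs of a simulator step (already normalized).

    coords are centred on the unit centroid and scaled by the mean section
    radius; concentrations are scaled by ``c_scale`` (the inlet concentration
    unless stated otherwise); the parameter vector is passed as-is.
    """

    coords: np.ndarray          # (N, 3) centred, μm
    params_vec: np.ndarray      # (N, 8)
    c: np.ndarray               # (N, 2) normalized (c0, c+)
    c_scale: float
    inlet_nodes: np.ndarray
    inlet_values: tuple[float, float]   # normalized (c0, c+) Dirichlet pair
    dirs: np.ndarray | None = None      # (N, 3) unit flow directions

    @property
    def x(self) -> np.ndarray:
        return np.hstack([self.coords, self.params_vec, self.c])


def make_features(g: TemplateGraph, params: SimulationParams,
                  state: ConcentrationState,
                  c_scale: float | None = None,
                  inlet_values: tuple[float, float] | None = None,
                  velocity: VelocityField | None = None) -> NodeFeatureSet:
    """Assemble the normalized feature set for one unit and state.

    Coordinates are centred on the unit centroid but kept in micrometres (a
    fixed 1 μm length scale), so the discrete-operator coefficients the
    network must learn are identical across units; the analytic node speeds
    (Poiseuille profile with flux splitting) enter as a parameter feature
    and their directions drive the upwind aggregation statistic.
    """
    from .solver import compute_velocity

    scale = c_scale if c_scale is not None else (params.c_in or 1.0)
    centroid = g.positions.mean(axis=0)
    coords = g.positions - centroid
    vf = velocity if velocity is not None else compute_velocity(g, params)
    speed = np.linalg.norm(vf.vectors, axis=1)
    dirs = np.zeros_like(vf.vectors)
    nz = speed > 0
    dirs[nz] = vf.vectors[nz] / speed[nz, None]
    pv = np.column_stack([
        np.full(g.n_nodes, params.D),
        np.full(g.n_nodes, params.k_plus),
        np.full(g.n_nodes, params.kp_plus),
        np.full(g.n_nodes, params.u_i),
        np.full(g.n_nodes, params.c_in if params.c_in is not None else 0.0),
        g.rfrac,
        g.node_radii,
        speed,
    ])
    c = np.column_stack([state.c0, state.c_plus]) / scale
    if inlet_values is None:
        cin = (params.c_in or 0.0) / scale
        inlet_values = (cin, params.lambda_in * cin)
    return NodeFeatureSet(coords=coords, params_vec=pv, c=c, c_scale=scale,
                          inlet_nodes=g.section_nodes(g.inlet_section),
                          inlet_values=inlet_values, dirs=dirs)


class SimulatorModel:
    """Recurrent GN-block + MLP-decoder simulator for one unit kind."""

    def __init__(self, kind: str, config: GNBlockConfig | None = None,
                 in_dim: int = 3 + N_PARAM_FEATURES + 2,
                 rng: np.random.Generator | None = None,
                 zero_decoder: bool = False):
        if rng is None:
            rng = np.random.default_rng(0)
        self.kind = kind
        self.config = config or GNBlockConfig()
        h = self.config.hidden
        self.in_dim = in_dim
        self.encoder = MLP([in_dim, h], rng)
        self.blocks = [MLP([h + N_AGG_FEATURES, h, h, h], rng)
                       for _ in range(self.config.n_steps)]
        self.decoder = MLP([h, h, h, h, 2], rng, zero_output=zero_decoder)

    # -- parameter plumbing ------------------------------------------------
    def modules(self):
        return [self.encoder, *self.blocks, self.decoder]

    def params(self):
        out = []
        for m in self.modules():
            out += m.W + m.b
        return out

    def grads(self):
        return [MLPGrads(m) for m in self.modules()]

    def copy(self) -> "SimulatorModel":
        return SimulatorModel.from_state(self.state_dict())

    def state_dict(self) -> dict:
        return {
            "kind": self.kind,
            "n_steps": self.config.n_steps,
            "hidden": self.config.hidden,
            "in_dim": self.in_dim,
            "modules": [m.state_dict() for m in self.modules()],
        }

    @classmethod
    def from_state(cls, state: dict) -> "SimulatorModel":
        m = cls.__new__(cls)
        m.kind = state["kind"]
        m.config = GNBlockConfig(n_steps=state["n_steps"], hidden=state["hidden"])
        m.in_dim = state["in_dim"]
        mods = [MLP.from_state(s) for s in state["modules"]]
        m.encoder = mods[0]
        m.blocks = mods[1:-1]
        m.decoder = mods[-1]
        return m

    def save(self, path) -> None:
        state = self.state_dict()
        arrays = {}
        for mi, mod in enumerate(state["modules"]):
            for k, w in enumerate(mod["W"]):
                arrays[f"m{mi}_W{k}"] = w
            for k, b in enumerate(mod["b"]):
                arrays[f"m{mi}_b{k}"] = b
        meta = {k: state[k] for k in ("kind", "n_steps", "hidden", "in_dim")}
        meta["dims"] = [mod["dims"] for mod in state["modules"]]
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SimulatorModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            modules = []
            for mi, dims in enumerate(meta["dims"]):
                nw = len(dims) - 1
                modules.append({
                    "dims": dims,
                    "W": [z[f"m{mi}_W{k}"] for k in range(nw)],
                    "b": [z[f"m{mi}_b{k}"] for k in range(nw)],
                })
        return cls.from_state({"kind": meta["kind"], "n_steps": meta["n_steps"],
                               "hidden": meta["hidden"], "in_dim": meta["in_dim"],
                               "modules": modules})

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray, agg: np.ndarray, caches: list | None = None):
        """Normalized prediction (N, 2) from stacked features and aggregated
        edge attributes; ``caches`` (a list) enables backprop."""
        cs = caches if caches is not None else None
        c_enc = [] if cs is not None else None
        h = self.encoder.forward(x, c_enc)
        if cs is not None:
            cs.append(c_enc)
        for blk in self.blocks:
            c_blk = [] if cs is not None else None
            h = blk.forward(np.hstack([h, agg]), c_blk)
            if cs is not None:
                cs.append(c_blk)
        c_dec = [] if cs is not None else None
        out = self.decoder.forward(h, c_dec)
        if cs is not None:
            cs.append(c_dec)
        return out

    def backward(self, dout: np.ndarray, caches: list, grads: list) -> None:
        """Accumulate parameter gradients for a forward pass recorded in
        ``caches``; ``grads`` matches :meth:`grads`."""
        h = self.config.hidden
        d = self.decoder.backward(dout, caches[-1], grads[-1])
        for k in range(len(self.blocks) - 1, -1, -1):
            d_in = self.blocks[k].backward(d, caches[1 + k], grads[1 + k])
            d = d_in[:, :h]
        self.encoder.backward(d, caches[0], grads[0])


def gn_block_forward(block: MLP, embeddings: np.ndarray, agg: np.ndarray) -> np.ndarray:
    """One GN step: concatenate each node's embedding with its aggregated
    edge attributes and apply the node MLP."""
    return block.forward(np.hstack([embeddings, agg]))


def _predict(model: SimulatorModel, g: TemplateGraph, feats: NodeFeatureSet):
    agg = aggregate_edge_features(feats.coords, feats.c, g.edges, dirs=feats.dirs)
    out = model.forward(feats.x, agg)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError(
            f"NaN/Inf in simulator output (kind={model.kind}, N={g.n_nodes})")
    out = out.copy()
    out[feats.inlet_nodes, 0] = feats.inlet_values[0]
    out[feats.inlet_nodes, 1] = feats.inlet_values[1]
    return out


def simulator_step(model: SimulatorModel, g: TemplateGraph,
                   feats: NodeFeatureSet) -> tuple[np.ndarray, np.ndarray]:
    """One learned time step; returns de-normalized (c0, c+) at t_{k+1} with
    the inlet Dirichlet values re-imposed."""
    out = _predict(model, g, feats) * feats.c_scale
    return out[:, 0], out[:, 1]


def _physical_bounds(feats: NodeFeatureSet, headroom: float = 1.05):
    """Invariant-region bounds of the transport model for this rollout.

    With Dirichlet inlet values and initial data below them, the continuous
    model keeps ``c0 ≤ max(c0_in, c0(0))`` and ``c+ ≤ max(c+_in, c+(0))``
    (maximum principle: diffusion and upwind advection are monotone and the
    reaction exchanges mass between the fields at ratio k₊/k₊′ ≤ λ).
    Rollout predictions are projected into this region — with a small
    headroom — so learned-simulator drift cannot diverge."""
    ub0 = headroom * max(float(np.max(feats.inlet_values[0])),
                         float(feats.c[:, 0].max()), 1e-12)
    ub1 = headroom * max(float(np.max(feats.inlet_values[1])),
                         float(feats.c[:, 1].max()), 1e-12)
    return np.array([ub0, ub1])


def rollout(model: SimulatorModel, g: TemplateGraph, feats: NodeFeatureSet,
            n_steps: int, dt: float = 0.1) -> list[ConcentrationState]:
    """Autoregressive rollout: each prediction becomes the next input;
    returns ``n_steps + 1`` states including the initial one.  Predictions
    are clipped to the model's physical invariant region (non-negative and
    below the inlet-determined maxima)."""
    c = feats.c.copy()
    states = [ConcentrationState(c[:, 0] * feats.c_scale, c[:, 1] * feats.c_scale, 0.0)]
    f = feats
    ub = _physical_bounds(feats)
    for k in range(n_steps):
        out = np.clip(_predict(model, g, f), 0.0, ub)
        ref = max(1.0, float(np.abs(f.c).max()))
        if np.abs(out).max() > 1e6 * ref:
            raise FloatingPointError("rollout diverged")
        f = NodeFeatureSet(coords=f.coords, params_vec=f.params_vec, c=out,
                           c_scale=f.c_scale, inlet_nodes=f.inlet_nodes,
                           inlet_values=f.inlet_values, dirs=f.dirs)
        states.append(ConcentrationState(out[:, 0] * f.c_scale,
                                         out[:, 1] * f.c_scale, (k + 1) * dt))
    return states


# ---------------------------------------------------------------------------
# physics-informed loss
# ---------------------------------------------------------------------------

def _as_fields(x) -> np.ndarray:
    if isinstance(x, ConcentrationState):
        return np.column_stack([x.c0, x.c_plus])
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        raise ValueError("expected (N, 2) fields or a ConcentrationState")
    return x


def simulator_loss(pred, truth, prev, g: TemplateGraph, params: SimulationParams,
                   v: VelocityField | None = None,
                   include_residuals: bool = True,
                   ops: Operators | None = None,
                   residual_form: str = "explicit",
                   return_grad: bool = False):
    """Physics-informed simulator loss.

    ``mean[(Δc0)² + (Δc+)²]`` over nodes, plus — when residual terms are
    enabled — the mean squared residual of each governing transport
    equation with ``∂c/∂t ≈ (pred − prev)/dt`` and the reference solver's
    discrete Laplacian and upwind-gradient operators, evaluated on the
    interior (non-Dirichlet) nodes.

    The time level of the spatial/reaction terms is a discretization choice:
    ``residual_form="explicit"`` (default) evaluates them on the known state
    at t_k — a forward-Euler residual, which keeps the loss well conditioned
    because the stiff operators never multiply the prediction —
    while ``"implicit"`` evaluates them on the prediction itself.
    With ``return_grad`` also returns dloss/dpred.
    """
    P, T, B = _as_fields(pred), _as_fields(truth), _as_fields(prev)
    n = len(P)
    diff = P - T
    loss = float(np.mean(diff[:, 0] ** 2 + diff[:, 1] ** 2))
    grad = 2.0 * diff / n if return_grad else None

    if include_residuals:
        if ops is None:
            if v is None:
                raise ValueError("residual terms require a velocity field or operators")
            ops = build_operators(g, v, params)
        if residual_form not in ("explicit", "implicit"):
            raise ValueError("residual_form must be 'explicit' or 'implicit'")
        dt = params.dt
        m = ops.interior
        nint = max(int(m.sum()), 1)
        S = P if residual_form == "implicit" else B
        r0 = ((P[:, 0] - B[:, 0]) / dt - params.D * (ops.lap @ S[:, 0])
              + params.k_plus * S[:, 0] - params.kp_plus * S[:, 1])
        r1 = ((P[:, 1] - B[:, 1]) / dt - (ops.adv @ S[:, 1])
              - params.k_plus * S[:, 0] + params.kp_plus * S[:, 1])
        r0m = np.where(m, r0, 0.0)
        r1m = np.where(m, r1, 0.0)
        loss += float(np.sum(r0m ** 2) + np.sum(r1m ** 2)) / nint
        if return_grad:
            s = 2.0 / nint
            if residual_form == "implicit":
                # r0 = (1/dt) c0 - D L c0 + k+ c0 - k'+ c+  (+ const)
                g0 = s * ((1.0 / dt + params.k_plus) * r0m
                          - params.D * (ops.lap.T @ r0m))
                g0 += s * (-params.k_plus) * r1m
                # r1 = (1/dt) c+ - A c+ + k'+ c+ - k+ c0  (+ const)
                g1 = s * ((1.0 / dt + params.kp_plus) * r1m - (ops.adv.T @ r1m))
                g1 += s * (-params.kp_plus) * r0m
            else:
                # prediction enters only through the time derivative
                g0 = s * r0m / dt
                g1 = s * r1m / dt
            grad = grad + np.column_stack([g0, g1])
    return (loss, grad) if return_grad else loss
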