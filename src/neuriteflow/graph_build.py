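"""Decomposition of a morphology into pipe / bifurcation units and the
construction of their template graphs.

A neurite tree is split into the two unit geometries the surrogate models
operate on: *pipes* (unbranched segments) and *bifurcations* (a 3-way branch
point together with three short stubs, three cross sections per stub).  Units
meet at *interfaces* — shared cross sections whose node positions coincide
exactly between the two owning units.

Each unit is turned into a template graph: cross sections along the
centerline, 17 nodes per ordinary section (1 center + 8 at r = R/2 + 8 at
r = R) and 23 nodes at a bifurcation branch point (the 17-node template plus
6 extra wall nodes facing the three joining branches).  Within a section,
edges form spokes and rings; between adjacent sections, nodes of equal
template index are linked, giving every interior node tangential and axial
neighbours for gradient estimation.

Cross-section frames (tangent / normal / binormal) are computed once per
morphology by parallel transport from the root, so frames are stable along
curved neurites and the two units owning an interface see the same frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .morphology import Morphology

__all__ = [
    "Section",
    "PipeUnit",
    "BifurcationUnit",
    "StructureGraph",
    "TemplateGraph",
    "DecompositionError",
    "decompose",
    "export_edge_list",
    "build_pipe_graph",
    "build_bifurcation_graph",
    "build_unit_graph",
]

N_SECTION = 17      # nodes per ordinary cross section
N_BRANCH_SECTION = 23  # nodes at the branch-point cross section
_RING = 8
_INNER_R = 0.5


class DecompositionError(ValueError):
    """A morphology cannot be decomposed into valid units."""


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(v):
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def _first_normal(t):
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(t, a))


def _transport(n, t_old, t_new):
    """Parallel-transport normal n from tangent t_old to t_new."""
    c = np.cross(t_old, t_new)
    s = np.linalg.norm(c)
    if s < 1e-12:
        out = n.copy()
    else:
        axis = c / s
        cos = float(np.clip(np.dot(t_old, t_new), -1.0, 1.0))
        sin = s
        out = (n * cos + np.cross(axis, n) * sin + axis * np.dot(axis, n) * (1 - cos))
    out = out - np.dot(out, t_new) * t_new
    return _unit(out)


def _rotate_about(v, axis, ang):
    axis = _unit(axis)
    return (v * np.cos(ang) + np.cross(axis, v) * np.sin(ang)
            + axis * np.dot(axis, v) * (1 - np.cos(ang)))


@dataclass
class Section:
    """One circular cross section: center, unit tangent (flow direction,
    root → tips), unit in-plane reference normal, radius (μm)."""

    center: np.ndarray
    tangent: np.ndarray
    normal: np.ndarray
    radius: float

    @property
    def binormal(self) -> np.ndarray:
        return np.cross(self.tangent, self.normal)

    def template_nodes(self, angle_offset: float = 0.0) -> np.ndarray:
        """Positions of the 17 base template nodes (center, inner ring,
        outer ring; rings at 45-degree steps from ``angle_offset``)."""
        b = self.binormal
        pts = [self.center]
        for rf in (_INNER_R, 1.0):
            for k in range(_RING):
                th = angle_offset + 2 * np.pi * k / _RING
                pts.append(self.center + self.radius * rf
                           * (np.cos(th) * self.normal + np.sin(th) * b))
        return np.array(pts)


_BASE_RFRAC = np.array([0.0] + [_INNER_R] * _RING + [1.0] * _RING)


# ---------------------------------------------------------------------------
# units
# ---------------------------------------------------------------------------

@dataclass
class PipeUnit:
    """An unbranched segment: centerline samples with radii and transported
    frames.  Index 0 is the upstream (root-facing) end."""

    unit_id: int
    centerline: np.ndarray   # (M, 3)
    radii: np.ndarray        # (M,)
    tangents: np.ndarray     # (M, 3), oriented downstream
    normals: np.ndarray      # (M, 3)
    iface_in: int | None = None
    iface_out: int | None = None
    kind: str = "pipe"

    @property
    def arc(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])


@dataclass
class BifurcationUnit:
    """A 3-way branch point with three stubs of three cross sections each.

    ``parent_sections`` are ordered upstream → branch point; child sections
    branch point → downstream.  ``bp_section`` is the 23-node section at the
    branch point itself; ``junction_angles`` are the in-plane angles (w.r.t.
    the bp frame) of the parent and two child branches, fixing where the six
    extra wall nodes sit.
    """

    unit_id: int
    branch_point: np.ndarray
    parent_sections: list[Section]
    child_sections: tuple[list[Section], list[Section]]
    bp_section: Section
    junction_angles: np.ndarray  # (3,) parent, child0, child1
    iface_in: int | None = None
    iface_out: tuple[int | None, int | None] = (None, None)
    kind: str = "bifurcation"

    def __post_init__(self):
        if len(self.parent_sections) != 3:
            raise ValueError("bifurcation needs exactly 3 parent sections")
        for cs in self.child_sections:
            if len(cs) != 3:
                raise ValueError("each branch needs exactly 3 cross sections")


@dataclass
class StructureGraph:
    """Decomposed morphology: units, unit adjacency, shared interfaces."""

    units: list
    adjacency: list[tuple[int, int, int]]          # (unit_a, unit_b, iface_id)
    interfaces: dict[int, Section]
    root_unit: int = 0

    def unit(self, uid: int):
        return self.units[uid]

    def neighbors(self, uid: int):
        out = []
        for a, b, i in self.adjacency:
            if a == uid:
                out.append((b, i))
            elif b == uid:
                out.append((a, i))
        return out

    @property
    def n_pipes(self) -> int:
        return sum(1 for u in self.units if u.kind == "pipe")

    @property
    def n_bifurcations(self) -> int:
        return sum(1 for u in self.units if u.kind == "bifurcation")


# ---------------------------------------------------------------------------
# template graphs
# ---------------------------------------------------------------------------

@dataclass
class TemplateGraph:
    """GNN-ready graph for one unit.

    Node roles are ``interior``, ``inlet``, ``outlet`` or ``interface``; for
    interface nodes ``interface_ids`` carries the interface id.  Per-section
    arrays describe centers/tangents/radii and the upstream section index
    used for flux propagation (-1 for the unit's inlet section).
    """

    kind: str
    unit_id: int
    positions: np.ndarray          # (N, 3)
    node_section: np.ndarray       # (N,)
    node_template_index: np.ndarray  # (N,)
    rfrac: np.ndarray              # (N,) distance from section center / R
    node_radii: np.ndarray         # (N,) radius of the node's section
    edges: np.ndarray              # (E, 2) undirected
    roles: np.ndarray              # (N,) str
    interface_ids: np.ndarray      # (N,) object
    section_centers: np.ndarray    # (S, 3)
    section_tangents: np.ndarray   # (S, 3)
    section_radii: np.ndarray      # (S,)
    section_upstream: np.ndarray   # (S,)
    inlet_section: int
    outlet_sections: list[int]
    section_split: np.ndarray | None = None  # (S,) child-split group, bif only

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_sections(self) -> int:
        return len(self.section_radii)

    def section_nodes(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.node_section == s)

    def interface_nodes(self, iface_id: int) -> np.ndarray:
        """Node indices on an interface, sorted by template index so both
        owning units enumerate them identically."""
        sel = np.flatnonzero(self.interface_ids == iface_id)
        return sel[np.argsort(self.node_template_index[sel])]

    def boundary_sections(self):
        return [self.inlet_section] + list(self.outlet_sections)

    # -- serialization ----------------------------------------------------
    def to_hdf5(self, group) -> None:
        str_dt = "S32"
        group.attrs["kind"] = self.kind
        group.attrs["unit_id"] = self.unit_id
        group.attrs["inlet_section"] = self.inlet_section
        group.attrs["outlet_sections"] = np.asarray(self.outlet_sections, dtype=np.int64)
        for name in ("positions", "node_section", "node_template_index", "rfrac",
                     "node_radii", "edges", "section_centers", "section_tangents",
                     "section_radii", "section_upstream"):
            group.create_dataset(name, data=getattr(self, name))
        group.create_dataset("roles", data=self.roles.astype(str_dt))
        iface = np.array([-1 if v is None else int(v) for v in self.interface_ids])
        group.create_dataset("interface_ids", data=iface)

    @classmethod
    def from_hdf5(cls, group) -> "TemplateGraph":
        iface_raw = group["interface_ids"][()]
        iface = np.array([None if v < 0 else int(v) for v in iface_raw], dtype=object)
        return cls(
            kind=str(group.attrs["kind"]),
            unit_id=int(group.attrs["unit_id"]),
            positions=group["positions"][()],
            node_section=group["node_section"][()],
            node_template_index=group["node_template_index"][()],
            rfrac=group["rfrac"][()],
            node_radii=group["node_radii"][()],
            edges=group["edges"][()],
            roles=group["roles"][()].astype(str),
            interface_ids=iface,
            section_centers=group["section_centers"][()],
            section_tangents=group["section_tangents"][()],
            section_radii=group["section_radii"][()],
            section_upstream=group["section_upstream"][()],
            inlet_section=int(group.attrs["inlet_section"]),
            outlet_sections=list(group.attrs["outlet_sections"]),
        )


def _section_edges(offset: int, n_nodes: int = N_SECTION) -> list[tuple[int, int]]:
    """In-section edges of the base 17-node template (indices + offset)."""
    e = []
    for k in range(_RING):
        e.append((offset, offset + 1 + k))                       # spokes
        e.append((offset + 1 + k, offset + 1 + (k + 1) % _RING))  # inner ring
        e.append((offset + 1 + k, offset + 9 + k))                # radial
        e.append((offset + 9 + k, offset + 9 + (k + 1) % _RING))  # outer ring
    return e


def _axial_edges(off_a: int, off_b: int) -> list[tuple[int, int]]:
    return [(off_a + k, off_b + k) for k in range(N_SECTION)]


def _stack_sections(sections: list[Section], angle_offsets=None):
    """Node positions + bookkeeping arrays for a run of 17-node sections."""
    if angle_offsets is None:
        angle_offsets = [0.0] * len(sections)
    pos, sec_idx, tmpl_idx = [], [], []
    for s, (sec, off) in enumerate(zip(sections, angle_offsets)):
        pos.append(sec.template_nodes(off))
        sec_idx.append(np.full(N_SECTION, s))
        tmpl_idx.append(np.arange(N_SECTION))
    return np.concatenate(pos), np.concatenate(sec_idx), np.concatenate(tmpl_idx)


def build_pipe_graph(p: PipeUnit, section_spacing: float | None = None) -> TemplateGraph:
    """Template graph of a pipe: ``m = max(2, ceil(L / spacing) + 1)`` evenly
    spaced cross sections of 17 nodes each.

    The default spacing is twice the local (mean) radius.  End sections sit
    exactly at the stored end frames, so interface nodes coincide with the
    neighbouring unit's; interior frames are parallel-transported from the
    upstream end with the residual twist distributed linearly so the
    downstream end frame is also met exactly.
    """
    L = p.length
    if L <= 0:
        raise DecompositionError(f"pipe {p.unit_id} has zero length")
    spacing = section_spacing if section_spacing is not None else 2.0 * float(np.mean(p.radii))
    m = max(2, int(np.ceil(L / spacing)) + 1)
    arc = p.arc
    s_new = np.linspace(0.0, L, m)

    centers = np.column_stack([np.interp(s_new, arc, p.centerline[:, k]) for k in range(3)])
    radii = np.interp(s_new, arc, p.radii)
    tangents = np.column_stack([np.interp(s_new, arc, p.tangents[:, k]) for k in range(3)])
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # exact end frames
    tangents[0], tangents[-1] = p.tangents[0], p.tangents[-1]
    centers[0], centers[-1] = p.centerline[0], p.centerline[-1]
    radii[0], radii[-1] = p.radii[0], p.radii[-1]

    normals = np.empty_like(tangents)
    normals[0] = p.normals[0]
    for k in range(1, m):
        normals[k] = _transport(normals[k - 1], tangents[k - 1], tangents[k])
    # twist correction: rotate so the transported end normal matches the
    # stored one, distributing the angle linearly over the sections
    target = p.normals[-1]
    t_end = tangents[-1]
    cur = normals[-1]
    ang = float(np.arctan2(np.dot(np.cross(cur, target), t_end), np.dot(cur, target)))
    if abs(ang) > 1e-15:
        for k in range(1, m):
            normals[k] = _rotate_about(normals[k], tangents[k], ang * k / (m - 1))
        normals[-1] = target

    sections = [Section(centers[k], tangents[k], normals[k], float(radii[k]))
                for k in range(m)]
    pos, sec_idx, tmpl_idx = _stack_sections(sections)

    edges: list[tuple[int, int]] = []
    for s in range(m):
        edges += _section_edges(s * N_SECTION)
        if s + 1 < m:
            edges += _axial_edges(s * N_SECTION, (s + 1) * N_SECTION)

    roles = np.array(["interior"] * len(pos), dtype=object)
    iface = np.array([None] * len(pos), dtype=object)
    first, last = np.flatnonzero(sec_idx == 0), np.flatnonzero(sec_idx == m - 1)
    roles[first] = "interface" if p.iface_in is not None else "inlet"
    roles[last] = "interface" if p.iface_out is not None else "outlet"
    iface[first] = p.iface_in
    iface[last] = p.iface_out

    return TemplateGraph(
        kind="pipe",
        unit_id=p.unit_id,
        positions=pos,
        node_section=sec_idx,
        node_template_index=tmpl_idx,
        rfrac=np.tile(_BASE_RFRAC, m),
        node_radii=radii[sec_idx],
        edges=np.array(edges, dtype=np.int64),
        roles=roles.astype(str),
        interface_ids=iface,
        section_centers=centers,
        section_tangents=tangents,
        section_radii=radii,
        section_upstream=np.arange(-1, m - 1),
        inlet_section=0,
        outlet_sections=[m - 1],
    )


def build_bifurcation_graph(b: BifurcationUnit) -> TemplateGraph:
    """Template graph of a bifurcation: 23 nodes at the branch-point section
    plus 3 branches × 3 sections × 17 nodes = 176 nodes.

    The branch-point template anchors its rings to the bisector of the two
    child directions (so a symmetric Y yields a node set symmetric under
    swapping children) and adds two extra wall nodes astride each of the
    three junction directions.
    """
    bp = b.bp_section
    th_par, th_c0, th_c1 = (float(a) for a in b.junction_angles)
    # anchor: circular bisector of the child directions
    phi = float(np.arctan2(np.sin(th_c0) + np.sin(th_c1), np.cos(th_c0) + np.cos(th_c1)))

    # section order: parent far→near (0..2), branch point (3),
    # child0 near→far (4..6), child1 near→far (7..9)
    run_secs = b.parent_sections + b.child_sections[0] + b.child_sections[1]
    pos_r, sec_r, tmpl_r = _stack_sections(run_secs)
    sec_map = np.array([0, 1, 2, 4, 5, 6, 7, 8, 9])
    sec_r = sec_map[sec_r]

    # branch-point section: 17 base nodes (anchored at phi) + 6 extras
    base = bp.template_nodes(angle_offset=phi)
    bnorm = bp.binormal
    extra_angles = []
    for th in (th_par, th_c0, th_c1):
        extra_angles += [th - np.pi / 16, th + np.pi / 16]
    extras = np.array([bp.center + bp.radius * (np.cos(a) * bp.normal + np.sin(a) * bnorm)
                       for a in extra_angles])
    pos_bp = np.vstack([base, extras])
    sec_bp = np.full(N_BRANCH_SECTION, 3)
    tmpl_bp = np.arange(N_BRANCH_SECTION)

    positions = np.vstack([pos_r, pos_bp])
    node_section = np.concatenate([sec_r, sec_bp])
    node_tmpl = np.concatenate([tmpl_r, tmpl_bp])
    rfrac = np.concatenate([np.tile(_BASE_RFRAC, 9),
                            _BASE_RFRAC, np.ones(6)])

    # node index offsets per section, in storage order
    off = {s: int(np.flatnonzero(node_section == s)[0]) for s in range(10)}
    edges: list[tuple[int, int]] = []
    for s in range(10):
        if s == 3:
            edges += _section_edges(off[3])
            # extras: link each to the two angularly adjacent outer-ring nodes
            ring_angles = phi + 2 * np.pi * np.arange(_RING) / _RING
            for j, a in enumerate(extra_angles):
                d = np.angle(np.exp(1j * (ring_angles - a)))
                near = np.argsort(np.abs(d))[:2]
                for k in near:
                    edges.append((off[3] + 17 + j, off[3] + 9 + int(k)))
        else:
            edges += _section_edges(off[s])
    for sa, sb in ((0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (3, 7), (7, 8), (8, 9)):
        edges += _axial_edges(off[sa], off[sb])

    roles = np.array(["interior"] * len(positions), dtype=object)
    iface = np.array([None] * len(positions), dtype=object)
    ends = [(0, b.iface_in, "inlet"), (6, b.iface_out[0], "outlet"),
            (9, b.iface_out[1], "outlet")]
    for s, ifid, fallback in ends:
        sel = np.flatnonzero(node_section == s)
        roles[sel] = "interface" if ifid is not None else fallback
        iface[sel] = ifid

    # per-section arrays, already in section order 0..9 (parent run, branch
    # point, child runs)
    centers = np.array([s.center for s in run_secs[:3]] + [bp.center]
                       + [s.center for s in run_secs[3:]])
    tangents = np.array([s.tangent for s in run_secs[:3]] + [bp.tangent]
                        + [s.tangent for s in run_secs[3:]])
    radii = np.array([s.radius for s in run_secs[:3]] + [bp.radius]
                     + [s.radius for s in run_secs[3:]])

    upstream = np.array([-1, 0, 1, 2, 3, 4, 5, 3, 7, 8])
    split = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])

    return TemplateGraph(
        kind="bifurcation",
        unit_id=b.unit_id,
        positions=positions,
        node_section=node_section,
        node_template_index=node_tmpl,
        rfrac=rfrac,
        node_radii=radii[node_section],
        edges=np.array(edges, dtype=np.int64),
        roles=roles.astype(str),
        interface_ids=iface,
        section_centers=centers,
        section_tangents=tangents,
        section_radii=radii,
        section_upstream=upstream,
        inlet_section=0,
        outlet_sections=[6, 9],
        section_split=split,
    )


def export_edge_list(g: TemplateGraph, path) -> None:
    """Write the template-graph adjacency as a whitespace edge list
    (``node_i node_j length``), one edge per line."""
    with open(path, "w") as fh:
        for i, j in g.edges:
            ell = float(np.linalg.norm(g.positions[i] - g.positions[j]))
            fh.write(f"{int(i)} {int(j)} {ell:.9g}\n")


def build_unit_graph(unit, section_spacing: float | None = None) -> TemplateGraph:
    if unit.kind == "pipe":
        return build_pipe_graph(unit, section_spacing)
    return build_bifurcation_graph(unit)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def _split_polytomies(m: Morphology, spacing: float) -> Morphology:
    """Split skeleton nodes with more than two children into cascaded
    degree-3 branch points.

    The cascade offset is seven section spacings so the short branch between
    the two new branch points can still host each bifurcation's three
    claimed cross sections plus a minimal pipe.
    """
    children = m.children_map()
    if all(len(c) <= 2 for c in children.values()):
        return m
    ids = list(m.ids)
    types = list(m.type_codes)
    xyz = [p for p in m.xyz]
    rad = list(m.radii)
    par = list(m.parent_ids)
    idx = {int(i): k for k, i in enumerate(ids)}
    next_id = max(ids) + 1
    changed = True
    while changed:
        changed = False
        cmap: dict[int, list[int]] = {int(i): [] for i in ids}
        for i, p in zip(ids, par):
            if p != -1:
                cmap[int(p)].append(int(i))
        for v, kids in cmap.items():
            if len(kids) <= 2:
                continue
            keep, moved = kids[:1], kids[1:]
            d = _unit(np.mean([xyz[idx[c]] - xyz[idx[v]] for c in moved], axis=0)
                      + 1e-12 * np.array([0.0, 0.0, 1.0]))
            new = next_id
            next_id += 1
            ids.append(new)
            types.append(int(types[idx[v]]))
            xyz.append(xyz[idx[v]] + 7.0 * spacing * d)
            rad.append(rad[idx[v]])
            par.append(v)
            idx[new] = len(ids) - 1
            for c in moved:
                par[idx[c]] = new
            changed = True
            break
    return Morphology(ids=np.array(ids), type_codes=np.array(types),
                      xyz=np.array(xyz), radii=np.array(rad),
                      parent_ids=np.array(par))


def _extract_branches(m: Morphology):
    """Branches (maximal unbranched paths) as lists of point indices,
    ordered root → tips; returns (branches, start_node, end_node)."""
    idx = m.index_of()
    children = m.children_map()
    root = m.root_id
    branches = []
    stack = [(root, c) for c in children[root]]
    # handle root having 1 or 2 children: root with 2 children is treated as
    # a branch point reached by a zero-length parent branch -> unsupported;
    # the generator always gives the root a single trunk.
    if len(children[root]) > 1:
        raise DecompositionError("root must start a single trunk")
    while stack:
        start, first = stack.pop()
        path = [idx[start], idx[first]]
        cur = first
        while len(children[cur]) == 1:
            cur = children[cur][0]
            path.append(idx[cur])
        branches.append(path)
        for c in children[cur]:
            stack.append((cur, c))
    return branches


def decompose(m: Morphology, section_spacing: float | None = None,
              max_pipe_sections: int = 10) -> StructureGraph:
    """Decompose a morphology into pipe and bifurcation units.

    Each degree-3 branch point claims three cross sections along every
    incident branch (at 1, 2 and 3 section spacings); what remains becomes
    pipes.  The outermost claimed section of each stub is an interface shared
    with the adjacent pipe.  Long pipes are split at ``max_pipe_sections``
    sections, producing pipe–pipe interfaces.

    Raises :class:`DecompositionError` when a branch is too short to host
    the claimed sections plus a minimal pipe.
    """
    spacing_fn = (lambda r: section_spacing) if section_spacing is not None \
        else (lambda r: 2.0 * r)

    work = _split_polytomies(m, spacing_fn(float(np.mean(m.radii))) or 1.0)
    idx = work.index_of()
    children = work.children_map()
    branches = _extract_branches(work)

    # per-branch geometry with globally transported frames
    binfo = []
    # transported frame at each branch start, keyed by start point id
    frame_at: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    root = work.root_id
    for path in branches:
        pts = work.xyz[path]
        rad = work.radii[path]
        seg = np.diff(pts, axis=0)
        seglen = np.linalg.norm(seg, axis=1)
        if np.any(seglen == 0):
            keep = np.concatenate([[True], seglen > 0])
            pts, rad = pts[keep], rad[keep]
            seg = np.diff(pts, axis=0)
            seglen = np.linalg.norm(seg, axis=1)
        tan = np.empty_like(pts)
        tan[0] = _unit(seg[0])
        tan[-1] = _unit(seg[-1])
        for k in range(1, len(pts) - 1):
            tan[k] = _unit(_unit(seg[k - 1]) + _unit(seg[k]))
        start_id = int(work.ids[path[0]])
        if start_id == root and start_id not in frame_at:
            frame_at[start_id] = (tan[0], _first_normal(tan[0]))
        t0, n0 = frame_at[start_id]
        nor = np.empty_like(pts)
        nor[0] = _transport(n0, t0, tan[0])
        for k in range(1, len(pts)):
            nor[k] = _transport(nor[k - 1], tan[k - 1], tan[k])
        end_id = int(work.ids[path[-1]])
        frame_at.setdefault(end_id, (tan[-1], nor[-1]))
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
        binfo.append(dict(path=path, pts=pts, rad=rad, tan=tan, nor=nor, arc=arc,
                          start=start_id, end=end_id))

    def interp_section(bi, s) -> Section:
        arc, pts, rad, tan, nor = bi["arc"], bi["pts"], bi["rad"], bi["tan"], bi["nor"]
        s = float(np.clip(s, 0, arc[-1]))
        c = np.array([np.interp(s, arc, pts[:, k]) for k in range(3)])
        r = float(np.interp(s, arc, rad))
        k = int(np.searchsorted(arc, s, side="right") - 1)
        k = min(max(k, 0), len(arc) - 1)
        t = np.array([np.interp(s, arc, tan[:, j]) for j in range(3)])
        t = _unit(t)
        n = _transport(nor[k], tan[k], t)
        return Section(c, t, n, r)

    branch_point_ids = [int(i) for i in work.ids
                        if len(children[int(i)]) == 2 and int(work.parent_ids[idx[int(i)]]) != -1]
    is_bp = set(branch_point_ids)

    # claimed arc-length intervals per branch: (from_start, from_end)
    claims = {k: [0.0, 0.0] for k in range(len(binfo))}
    b_by_start: dict[int, list[int]] = {}
    b_by_end: dict[int, int] = {}
    for k, bi in enumerate(binfo):
        b_by_start.setdefault(bi["start"], []).append(k)
        b_by_end[bi["end"]] = k

    units: list = []
    adjacency: list[tuple[int, int, int]] = []
    interfaces: dict[int, Section] = {}
    next_iface = 0
    # bookkeeping: for each branch, the pipe span and interface ids at ends
    pipe_span: dict[int, list] = {}

    bif_of_bp: dict[int, int] = {}
    bif_iface: dict[int, dict] = {}

    for bp_id in branch_point_ids:
        pbr = b_by_end[bp_id]
        cbrs = b_by_start.get(bp_id, [])
        if len(cbrs) != 2:
            raise DecompositionError(f"branch point {bp_id} lacks two child branches")
        sp = spacing_fn(float(work.radii[idx[bp_id]]))
        # feasibility: claimed length + room for at least half a spacing of pipe
        for k, from_end in ((pbr, True), (cbrs[0], False), (cbrs[1], False)):
            L = binfo[k]["arc"][-1]
            other = claims[k][0 if from_end else 1]
            if L - other - 3 * sp < 0.25 * sp:
                raise DecompositionError(
                    f"branch at point {bp_id} too short ({L:.2f} μm) for a "
                    f"bifurcation's 3 cross sections at spacing {sp:.2f} μm")
        bi_p = binfo[pbr]
        Lp = bi_p["arc"][-1]
        parent_secs = [interp_section(bi_p, Lp - d * sp) for d in (3, 2, 1)]
        child_secs = tuple([interp_section(binfo[c], d * sp) for d in (1, 2, 3)]
                           for c in cbrs)
        claims[pbr][1] = 3 * sp
        for c in cbrs:
            claims[c][0] = 3 * sp

        bp_sec = interp_section(bi_p, Lp)
        # junction angles in the bp frame
        nrm, bno = bp_sec.normal, bp_sec.binormal

        def plane_angle(v, fallback):
            x, y = np.dot(v, nrm), np.dot(v, bno)
            if x * x + y * y < 1e-16:
                return fallback
            return float(np.arctan2(y, x))

        a_c0 = plane_angle(binfo[cbrs[0]]["tan"][0], 0.0)
        a_c1 = plane_angle(binfo[cbrs[1]]["tan"][0], np.pi)
        phi = float(np.arctan2(np.sin(a_c0) + np.sin(a_c1),
                               np.cos(a_c0) + np.cos(a_c1)))
        a_par = plane_angle(-bi_p["tan"][-1], phi + np.pi)

        uid = len(units)
        iface_in = next_iface
        interfaces[iface_in] = parent_secs[0]
        next_iface += 1
        if_c = []
        for cs in child_secs:
            interfaces[next_iface] = cs[2]
            if_c.append(next_iface)
            next_iface += 1
        unit = BifurcationUnit(
            unit_id=uid, branch_point=bp_sec.center,
            parent_sections=parent_secs, child_sections=child_secs,
            bp_section=bp_sec, junction_angles=np.array([a_par, a_c0, a_c1]),
            iface_in=iface_in, iface_out=(if_c[0], if_c[1]),
        )
        units.append(unit)
        bif_of_bp[bp_id] = uid
        bif_iface[bp_id] = dict(parent=iface_in, children=dict(zip(cbrs, if_c)))

    # pipes on the unclaimed branch spans
    for k, bi in enumerate(binfo):
        L = bi["arc"][-1]
        s0, s1 = claims[k][0], L - claims[k][1]
        if s1 - s0 <= 1e-9:
            raise DecompositionError("no room left for a pipe on a branch")
        iface_in = bif_iface[bi["start"]]["children"][k] if bi["start"] in bif_of_bp else None
        iface_out = bif_iface[bi["end"]]["parent"] if bi["end"] in is_bp else None

        sp = spacing_fn(float(np.mean(bi["rad"])))
        n_parts = max(1, int(np.ceil((s1 - s0) / (max_pipe_sections * sp))))
        cuts = np.linspace(s0, s1, n_parts + 1)
        prev_iface = iface_in
        for q in range(n_parts):
            a, bnd = cuts[q], cuts[q + 1]
            dense = np.linspace(a, bnd, max(2, int(np.ceil((bnd - a) / (0.5 * sp))) + 1))
            secs = [interp_section(bi, s) for s in dense]
            out_if = iface_out if q == n_parts - 1 else next_iface
            if q < n_parts - 1:
                interfaces[next_iface] = secs[-1]
                next_iface += 1
            uid = len(units)
            # pin end sections to registered interface frames for exact overlap
            if prev_iface is not None:
                secs[0] = interfaces[prev_iface]
            if out_if is not None:
                secs[-1] = interfaces[out_if]
            unit = PipeUnit(
                unit_id=uid,
                centerline=np.array([s.center for s in secs]),
                radii=np.array([s.radius for s in secs]),
                tangents=np.array([s.tangent for s in secs]),
                normals=np.array([s.normal for s in secs]),
                iface_in=prev_iface, iface_out=out_if,
            )
            units.append(unit)
            prev_iface = out_if

    # adjacency from shared interface ids
    owners: dict[int, list[int]] = {}
    for u in units:
        ifs = [u.iface_in] + (list(u.iface_out) if u.kind == "bifurcation" else [u.iface_out])
        for i in ifs:
            if i is not None:
                owners.setdefault(i, []).append(u.unit_id)
    for i, os_ in owners.items():
        if len(os_) != 2:
            raise DecompositionError(f"interface {i} owned by {len(os_)} units")
        adjacency.append((os_[0], os_[1], i))

    root_unit = next(u.unit_id for u in units
                     if (u.kind == "pipe" and u.iface_in is None)
                     or (u.kind == "bifurcation" and u.iface_in is None))
    return StructureGraph(units=units, adjacency=adjacency,
                          interfaces=interfaces, root_unit=root_unit)
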