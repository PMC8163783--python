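"""Neuron morphologies: SWC input/output and synthetic branched trees.

A morphology is a rooted skeleton tree of 3D sample points with per-point
radii, the standard representation used by morphology databases.  The SWC
dialect implemented here is the NeuroMorpho one: seven whitespace-separated
columns ``id type x y z radius parent``, 1-based integer ids, parent ``-1``
for the root, ``#`` comment lines.  Positions and radii are in micrometres.

The synthetic generator grows random binary trees with tapering radii so the
rest of the pipeline (decomposition, solving, training) can be exercised
without downloading real neurons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Morphology",
    "MorphologySpec",
    "MorphologyError",
    "SwcParseError",
    "read_swc",
    "write_swc",
    "generate_morphology",
    "resample_polyline",
]


class MorphologyError(ValueError):
    """Structural or validation problem with a morphology."""


class SwcParseError(MorphologyError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class Morphology:
    """Rooted skeleton tree of 3D points with radii.

    Attributes
    ----------
    ids : (N,) int array of point identifiers (unique).
    type_codes : (N,) int array; SWC structure codes, preserved verbatim.
    xyz : (N, 3) float array, micrometres.
    radii : (N,) float array, micrometres, strictly positive.
    parent_ids : (N,) int array; ``-1`` marks the single root.
    """

    ids: np.ndarray
    type_codes: np.ndarray
    xyz: np.ndarray
    radii: np.ndarray
    parent_ids: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.type_codes = np.asarray(self.type_codes, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.radii = np.asarray(self.radii, dtype=np.float64)
        self.parent_ids = np.asarray(self.parent_ids, dtype=np.int64)
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.ids)

    def index_of(self) -> dict[int, int]:
        return {int(i): k for k, i in enumerate(self.ids)}

    def children_map(self) -> dict[int, list[int]]:
        """Map point id -> list of child ids (declaration order)."""
        out: dict[int, list[int]] = {int(i): [] for i in self.ids}
        for i, p in zip(self.ids, self.parent_ids):
            if p != -1:
                out[int(p)].append(int(i))
        return out

    @property
    def root_id(self) -> int:
        roots = self.ids[self.parent_ids == -1]
        return int(roots[0])

    def validate(self) -> None:
        if self.n_points == 0:
            raise MorphologyError("empty morphology")
        if len(np.unique(self.ids)) != self.n_points:
            raise MorphologyError("duplicate point ids")
        roots = np.flatnonzero(self.parent_ids == -1)
        if len(roots) != 1:
            raise MorphologyError(f"expected exactly one root, found {len(roots)}")
        if not np.all(np.isfinite(self.xyz)):
            raise MorphologyError("non-finite coordinates")
        if not np.all(np.isfinite(self.radii)) or np.any(self.radii <= 0):
            raise MorphologyError("radii must be finite and strictly positive")
        idx = self.index_of()
        for i, p in zip(self.ids, self.parent_ids):
            if p == -1:
                continue
            if int(p) not in idx:
                raise MorphologyError(f"point {int(i)} references unknown parent {int(p)}")
            if int(p) == int(i):
                raise MorphologyError(f"point {int(i)} is its own parent")
        # cycle check: walk each point to the root, bounded by n_points hops
        n = self.n_points
        parent_idx = np.array(
            [idx[int(p)] if p != -1 else -1 for p in self.parent_ids], dtype=np.int64
        )
        for k in range(n):
            seen = 0
            j = k
            while j != -1:
                j = int(parent_idx[j])
                seen += 1
                if seen > n:
                    raise MorphologyError(f"cycle detected through point {int(self.ids[k])}")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "ids": self.ids.tolist(),
                "type_codes": self.type_codes.tolist(),
                "xyz": self.xyz.tolist(),
                "radii": self.radii.tolist(),
                "parent_ids": self.parent_ids.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Morphology":
        d = json.loads(text)
        return cls(
            ids=np.array(d["ids"]),
            type_codes=np.array(d["type_codes"]),
            xyz=np.array(d["xyz"]),
            radii=np.array(d["radii"]),
            parent_ids=np.array(d["parent_ids"]),
        )

    def equivalent_to(self, other: "Morphology", tol: float = 1e-9) -> bool:
        """Topology/geometry equality, tolerant to id remapping.

        Points are compared in a canonical depth-first order from the root.
        """
        a, b = _canonical_order(self), _canonical_order(other)
        if a[0].shape != b[0].shape:
            return False
        xyz_a, rad_a, par_a = a
        xyz_b, rad_b, par_b = b
        return (
            np.allclose(xyz_a, xyz_b, atol=tol)
            and np.allclose(rad_a, rad_b, atol=tol)
            and np.array_equal(par_a, par_b)
        )


def _canonical_order(m: Morphology):
    idx = m.index_of()
    children = m.children_map()
    order: list[int] = []
    parent_pos: list[int] = []
    stack = [(m.root_id, -1)]
    while stack:
        nid, ppos = stack.pop()
        pos = len(order)
        order.append(idx[nid])
        parent_pos.append(ppos)
        # deterministic child order: by declaration
        for c in reversed(children[nid]):
            stack.append((c, pos))
    sel = np.array(order)
    return m.xyz[sel], m.radii[sel], np.array(parent_pos)


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path: str | Path) -> Morphology:
    """Parse an SWC file (NeuroMorpho dialect).

    Comment lines starting with ``#`` and blank lines are skipped.  Raises
    :class:`SwcParseError` with the line number for malformed records and
    :class:`MorphologyError` for structural problems (cycles, dangling
    parents, non-positive radii, empty files).
    """
    rows = []
    with open(path, "r") as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SwcParseError(
                    f"expected 7 whitespace-separated fields, got {len(parts)}", ln
                )
            try:
                i = int(parts[0])
                t = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                p = int(parts[6])
            except ValueError as exc:
                raise SwcParseError(f"could not parse record: {exc}", ln) from exc
            rows.append((i, t, x, y, z, r, p))
    if not rows:
        raise MorphologyError(f"no data records in {path}")
    arr = np.array(rows, dtype=np.float64)
    return Morphology(
        ids=arr[:, 0].astype(np.int64),
        type_codes=arr[:, 1].astype(np.int64),
        xyz=arr[:, 2:5],
        radii=arr[:, 5],
        parent_ids=arr[:, 6].astype(np.int64),
    )


def write_swc(m: Morphology, path: str | Path, header: str | None = None) -> None:
    """Write a morphology in the 7-column SWC dialect (ids renumbered 1..N)."""
    idx = m.index_of()
    remap = {int(i): k + 1 for k, i in enumerate(m.ids)}
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for k in range(m.n_points):
            p = int(m.parent_ids[k])
            fh.write(
                "%d %d %.9g %.9g %.9g %.9g %d\n"
                % (
                    remap[int(m.ids[k])],
                    int(m.type_codes[k]),
                    m.xyz[k, 0],
                    m.xyz[k, 1],
                    m.xyz[k, 2],
                    m.radii[k],
                    -1 if p == -1 else remap[p],
                )
            )


# ---------------------------------------------------------------------------
# Synthetic morphology generation
# ---------------------------------------------------------------------------

@dataclass
class MorphologySpec:
    """Parameters of the synthetic branched-tree generator.

    n_bifurcations : number of 3-way branch points (binary tree, so the tree
        has ``n_bifurcations + 1`` tips).
    branch_length_range : (min, max) branch length in micrometres.
    radius_root : radius at the root cross section, micrometres.
    taper_ratio : multiplicative radius factor per branch order, in (0, 1].
    sampling_spacing : skeleton resampling step, micrometres.
    branch_angle_deg : half-angle between daughter branches at a bifurcation.
    wiggle : std of random perpendicular deflection per step (fraction of
        spacing); gives branches a gentle, realistic curvature.
    seed : generator seed; identical specs produce identical morphologies.
    """

    n_bifurcations: int = 1
    branch_length_range: tuple[float, float] = (12.0, 20.0)
    radius_root: float = 1.0
    taper_ratio: float = 0.85
    sampling_spacing: float = 1.0
    branch_angle_deg: float = 35.0
    wiggle: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.branch_length_range
        if lo > hi or lo <= 0:
            raise ValueError("branch_length_range must satisfy 0 < min <= max")
        if self.n_bifurcations < 0:
            raise ValueError("n_bifurcations must be >= 0")
        if self.radius_root <= 0:
            raise ValueError("radius_root must be positive")
        if not (0 < self.taper_ratio <= 1):
            raise ValueError("taper_ratio must lie in (0, 1]")
        if self.sampling_spacing <= 0:
            raise ValueError("sampling_spacing must be positive")
        if self.sampling_spacing > hi:
            raise ValueError("sampling_spacing exceeds the maximum branch length")


def resample_polyline(points: np.ndarray, values: np.ndarray, spacing: float):
    """Resample a polyline (and per-point scalars) at uniform arc length.

    Keeps the exact endpoints; the interior step is ``length / ceil(length /
    spacing)`` so the requested spacing is an upper bound.
    """
    points = np.asarray(points, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    length = s[-1]
    if length <= 0:
        raise ValueError("degenerate polyline (zero length)")
    n_seg = max(1, int(np.ceil(length / spacing)))
    snew = np.linspace(0.0, length, n_seg + 1)
    xyz = np.column_stack([np.interp(snew, s, points[:, k]) for k in range(3)])
    vals = np.interp(snew, s, values)
    return xyz, vals


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction")
    return v / n


def _perp_basis(t: np.ndarray):
    """Two unit vectors spanning the plane perpendicular to t."""
    a = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = _unit(np.cross(t, a))
    n2 = np.cross(t, n1)
    return n1, n2


def _random_topology(n_bif: int, rng: np.random.Generator) -> list[int]:
    """Random binary tree topology: returns parent-branch index per branch.

    Branch 0 is the trunk (parent -1); each bifurcation turns one open tip
    into two child branches.
    """
    parents = [-1]
    tips = [0]
    for _ in range(n_bif):
        k = int(rng.integers(len(tips)))
        b = tips.pop(k)
        parents.append(b)
        parents.append(b)
        tips.extend([len(parents) - 2, len(parents) - 1])
    return parents


def generate_morphology(spec: MorphologySpec) -> Morphology:
    """Grow a synthetic branched morphology per the spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    parents = _random_topology(spec.n_bifurcations, rng)
    n_branch = len(parents)

    # branch order = number of bifurcations on the path to the root
    order = [0] * n_branch
    for b in range(1, n_branch):
        order[b] = order[parents[b]] + 1

    lo, hi = spec.branch_length_range
    lengths = rng.uniform(lo, hi, size=n_branch)
    radii_b = spec.radius_root * spec.taper_ratio ** np.array(order, dtype=float)

    # grow geometry branch by branch
    start_pt: list[np.ndarray] = [np.zeros(3)] * n_branch
    start_dir: list[np.ndarray] = [np.array([0.0, 0.0, 1.0])] * n_branch
    branch_pts: list[np.ndarray] = [None] * n_branch  # type: ignore[list-item]

    children: dict[int, list[int]] = {b: [] for b in range(n_branch)}
    for b in range(1, n_branch):
        children[parents[b]].append(b)

    for b in range(n_branch):
        p0 = start_pt[b]
        d = start_dir[b].copy()
        n_steps = max(2, int(np.ceil(lengths[b] / spec.sampling_spacing)))
        step = lengths[b] / n_steps
        pts = [p0]
        for _ in range(n_steps):
            n1, n2 = _perp_basis(d)
            d = _unit(d + spec.wiggle * (rng.normal() * n1 + rng.normal() * n2))
            pts.append(pts[-1] + step * d)
        arr = np.array(pts)
        branch_pts[b] = arr
        kids = children[b]
        if kids:
            # daughters leave the branch end at +/- branch_angle around the
            # end direction, in a randomly rolled plane
            n1, n2 = _perp_basis(d)
            roll = rng.uniform(0, 2 * np.pi)
            perp = np.cos(roll) * n1 + np.sin(roll) * n2
            ang = np.deg2rad(spec.branch_angle_deg)
            for sgn, c in zip((+1.0, -1.0), kids):
                start_pt[c] = arr[-1]
                start_dir[c] = _unit(np.cos(ang) * d + sgn * np.sin(ang) * perp)

    # assemble SWC-style point list; branch starts reuse the parent's end point
    ids: list[int] = []
    types: list[int] = []
    xyz: list[np.ndarray] = []
    rad: list[float] = []
    par: list[int] = []
    end_id: dict[int, int] = {}
    next_id = 1

    def emit(pt, r, parent, tcode=3):
        nonlocal next_id
        ids.append(next_id)
        types.append(tcode)
        xyz.append(pt)
        rad.append(r)
        par.append(parent)
        next_id += 1
        return next_id - 1

    stack = [0]
    emitted: list[int] = []
    while stack:
        b = stack.pop()
        pts, _ = resample_polyline(branch_pts[b], np.full(len(branch_pts[b]), radii_b[b]),
                                   spec.sampling_spacing)
        if parents[b] == -1:
            parent = emit(pts[0], radii_b[b], -1, tcode=1)
        else:
            parent = end_id[parents[b]]
        for k in range(1, len(pts)):
            parent = emit(pts[k], radii_b[b], parent)
        end_id[b] = parent
        emitted.append(b)
        for c in reversed(children[b]):
            stack.append(c)

    return Morphology(
        ids=np.array(ids),
        type_codes=np.array(types),
        xyz=np.array(xyz),
        radii=np.array(rad),
        parent_ids=np.array(par),
    )
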