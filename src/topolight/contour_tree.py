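"""Contour trees of 3D scalar fields: merge trees, combination, branch
decomposition, importance-based simplification, and branch-indexed
segmentation.

The contour tree tracks how connected components of level sets of a scalar
field appear, merge, split and vanish as the isovalue sweeps the data range.
It is built here in the classic way: a join tree (superlevel-set components)
and a split tree (sublevel-set components) are computed by a sorted sweep with
union-find, then combined by iterative leaf transfer.  The branch
decomposition partitions the tree into monotone extremum-saddle paths with a
single root branch spanning the global extrema; child branches attach at
saddles interior to their parent's path.

Equal scalar values are totally ordered by (value, linear vertex index)
("simulation of simplicity"), so all critical events are distinct.

Connectivity follows the digital-topology duality: on a cubical grid the
superlevel and sublevel sides must use dual neighborhoods (6/26, the 3D
analogue of 4/8 in 2D images), otherwise the two merge trees can be
topologically incompatible (the "checkerboard" paradox) and no contour tree
realizes both.  ``build_contour_tree(connectivity=6)`` therefore builds the
join tree with 6-connectivity and the split tree with 26-connectivity;
``connectivity=26`` swaps the pair.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field as _dcfield

import numpy as np

from .field import ScalarField

__all__ = [
    "CriticalNode",
    "MergeTree",
    "ContourTree",
    "Branch",
    "BranchDecomposition",
    "SegmentationMap",
    "build_merge_tree",
    "combine_trees",
    "build_contour_tree",
    "decompose_branches",
    "simplify_tree",
    "segment_field",
    "IMPORTANCE_MEASURES",
]

IMPORTANCE_MEASURES = ("persistence", "volume", "hypervolume", "triangle_area")

_OFFSETS_6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def neighbor_table(dims: tuple[int, int, int], connectivity: int = 6) -> np.ndarray:
    """(n, k) array of neighbor linear indices; -1 marks out-of-bounds."""
    if connectivity not in (6, 26):
        raise ValueError(f"connectivity must be 6 or 26, got {connectivity}")
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    idx = np.arange(int(np.prod(dims)), dtype=np.int64).reshape(dims, order="F")
    cols = []
    for off in offsets:
        shifted = np.full(dims, -1, dtype=np.int64)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate(off):
            if d == 1:
                dst[ax] = slice(0, dims[ax] - 1)
                src[ax] = slice(1, dims[ax])
            elif d == -1:
                dst[ax] = slice(1, dims[ax])
                src[ax] = slice(0, dims[ax] - 1)
        shifted[tuple(dst)] = idx[tuple(src)]
        cols.append(shifted.ravel(order="F"))
    return np.stack(cols, axis=1)


class _UnionFind:
    __slots__ = ("parent",)

    def __init__(self, n: int) -> None:
        self.parent = np.arange(n, dtype=np.int64)

    def find(self, v: int) -> int:
        p = self.parent
        root = v
        while p[root] != root:
            root = p[root]
        while p[v] != root:  # path compression
            p[v], v = root, p[v]
        return int(root)

    def union(self, a: int, b: int) -> int:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
        return rb


@dataclass(frozen=True)
class CriticalNode:
    id: int
    vertex_index: int
    value: float
    kind: str  # "minimum" | "maximum" | "saddle"


@dataclass
class MergeTree:
    """Augmented merge tree: one node per grid vertex, parent pointers toward
    the sweep direction.

    For the join tree (``direction='ascending'``) parents point to lower
    vertices: superlevel-set components are born at maxima and merge at join
    saddles.  The split tree is the mirror image on sublevel sets.
    """

    field: ScalarField
    direction: str
    connectivity: int
    parent: np.ndarray  # (n,) linear vertex -> next vertex, -1 at the root

    @property
    def root_vertex(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    def child_counts(self) -> np.ndarray:
        n = self.parent.size
        return np.bincount(self.parent[self.parent >= 0], minlength=n)

    def leaves(self) -> np.ndarray:
        """Extremum vertices (no children in this tree)."""
        return np.nonzero(self.child_counts() == 0)[0]

    def reduced(self) -> tuple[list[int], list[tuple[int, int]]]:
        """(critical vertices, arcs) with regular (one-child, non-root)
        vertices contracted away."""
        counts = self.child_counts()
        critical = {v for v in range(self.parent.size)
                    if counts[v] != 1 or self.parent[v] < 0}
        arcs = []
        for v in sorted(critical):
            w = int(self.parent[v])
            while w >= 0 and w not in critical:
                w = int(self.parent[w])
            if w >= 0:
                arcs.append((v, w))
        return sorted(critical), arcs


def _validate_field(field: ScalarField) -> None:
    if all(d < 2 for d in field.dims):
        raise ValueError(f"grid too small in every axis: dims={field.dims}")


def build_merge_tree(
    field: ScalarField, direction: str = "ascending", connectivity: int = 6
) -> MergeTree:
    """Build the join tree (``ascending``) or split tree (``descending``) by a
    sorted sweep with union-find.

    The join tree sweeps vertices from high to low: each vertex starts a new
    superlevel-set component (a maximum) or attaches to / merges existing
    components (regular vertices / join saddles).
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be 'ascending' or 'descending', got {direction!r}")
    _validate_field(field)
    nbr = neighbor_table(field.dims, connectivity)
    order = field.total_order()
    if direction == "ascending":
        sweep = order[::-1]  # high to low: superlevel sets
    else:
        sweep = order
    n = field.n_vertices
    parent = np.full(n, -1, dtype=np.int64)
    uf = _UnionFind(n)
    frontier = np.arange(n, dtype=np.int64)  # open end of each component's arc
    processed = np.zeros(n, dtype=bool)
    for v in sweep:
        v = int(v)
        for u in nbr[v]:
            if u < 0 or not processed[u]:
                continue
            ru = uf.find(int(u))
            if ru == uf.find(v):
                continue
            parent[frontier[ru]] = v
            r = uf.union(ru, v)
            frontier[r] = v
        processed[v] = True
    return MergeTree(field=field, direction=direction,
                     connectivity=connectivity, parent=parent)


@dataclass(frozen=True)
class _Arc:
    """Reduced contour-tree arc between two critical nodes, with the regular
    grid vertices lying on its interior."""

    id: int
    top_node: int
    bottom_node: int
    interior: np.ndarray  # linear vertex indices, top to bottom


@dataclass
class ContourTree:
    field: ScalarField
    nodes: list[CriticalNode]
    arcs: list[_Arc]
    vertex_arc: np.ndarray  # (n,) regular vertex -> arc id; -1 for critical
    vertex_node: dict[int, int]  # critical vertex -> node id
    up_degree: np.ndarray  # per node id
    down_degree: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def arc_pairs(self) -> list[tuple[int, int]]:
        return [(a.top_node, a.bottom_node) for a in self.arcs]

    def leaves(self) -> list[CriticalNode]:
        return [nd for nd in self.nodes
                if self.up_degree[nd.id] + self.down_degree[nd.id] == 1]

    def saddles(self) -> list[CriticalNode]:
        return [nd for nd in self.nodes
                if self.up_degree[nd.id] + self.down_degree[nd.id] != 1]

    def to_dict(self) -> dict:
        return {
            "dims": list(self.field.dims),
            "nodes": [
                {"id": nd.id, "vertex_index": int(nd.vertex_index),
                 "value": nd.value, "kind": nd.kind}
                for nd in self.nodes
            ],
            "arcs": [[a.top_node, a.bottom_node] for a in self.arcs],
        }


def _constant_tree(field: ScalarField) -> ContourTree:
    # Degenerate constant field: a single-node tree; downstream stages treat
    # it as one root branch covering every voxel.
    node = CriticalNode(id=0, vertex_index=0, value=float(field.flat()[0]),
                        kind="maximum")
    return ContourTree(
        field=field, nodes=[node], arcs=[],
        vertex_arc=np.full(field.n_vertices, -1, dtype=np.int64),
        vertex_node={0: 0},
        up_degree=np.zeros(1, dtype=np.int64),
        down_degree=np.zeros(1, dtype=np.int64),
    )


def combine_trees(join: MergeTree, split: MergeTree) -> ContourTree:
    """Combine augmented join and split trees into the contour tree.

    Iteratively transfers vertices that are a leaf of one tree and regular in
    the other (Carr-style merge); the result is reduced to critical nodes,
    keeping a map from every regular grid vertex to its arc.
    """
    if join.field is not split.field and not (
        join.field.dims == split.field.dims
        and np.array_equal(join.field.values, split.field.values)
    ):
        raise ValueError("join and split trees were built over different vertex sets")
    field = join.field
    n = field.n_vertices
    if n == 1:
        return _constant_tree(field)
    fmin, fmax = field.value_range
    if fmin == fmax:
        return _constant_tree(field)

    jp = join.parent.copy()
    sp = split.parent.copy()
    jc = np.bincount(jp[jp >= 0], minlength=n)
    sc = np.bincount(sp[sp >= 0], minlength=n)
    jkids: list[list[int]] = [[] for _ in range(n)]
    skids: list[list[int]] = [[] for _ in range(n)]
    for w in range(n):
        if jp[w] >= 0:
            jkids[jp[w]].append(w)
        if sp[w] >= 0:
            skids[sp[w]].append(w)

    ct_up: list[list[int]] = [[] for _ in range(n)]
    ct_down: list[list[int]] = [[] for _ in range(n)]
    removed = np.zeros(n, dtype=bool)
    queue = deque(v for v in range(n) if jc[v] + sc[v] == 1)
    active = n
    while active > 1:
        if not queue:
            raise RuntimeError(
                "contour tree merge stalled: the join and split trees are "
                "topologically incompatible (this happens for symmetric "
                "connectivity on cubical grids; use the dual 6/26 pair as "
                "build_contour_tree does)")
        x = queue.popleft()
        if removed[x] or jc[x] + sc[x] != 1:
            continue
        if jc[x] == 0:  # upper leaf: arc descends to its join parent
            y = int(jp[x])
            ct_down[x].append(y)
            ct_up[y].append(x)
            jkids[y].remove(x)
            jc[y] -= 1
            # bypass x in the split tree (x is regular there)
            q = int(sp[x])
            if skids[x]:
                c = skids[x][0]
                sp[c] = q
                if q >= 0:
                    skids[q].remove(x)
                    skids[q].append(c)
            elif q >= 0:
                skids[q].remove(x)
                sc[q] -= 1
        else:  # lower leaf: arc ascends to its split parent
            y = int(sp[x])
            ct_up[x].append(y)
            ct_down[y].append(x)
            skids[y].remove(x)
            sc[y] -= 1
            q = int(jp[x])
            if jkids[x]:
                c = jkids[x][0]
                jp[c] = q
                if q >= 0:
                    jkids[q].remove(x)
                    jkids[q].append(c)
            elif q >= 0:
                jkids[q].remove(x)
                jc[q] -= 1
        removed[x] = True
        active -= 1
        if not removed[y] and jc[y] + sc[y] == 1:
            queue.append(y)

    return _reduce(field, ct_up, ct_down)


def _reduce(field: ScalarField, ct_up: list[list[int]],
            ct_down: list[list[int]]) -> ContourTree:
    n = field.n_vertices
    flat = field.flat()
    is_critical = np.fromiter(
        (len(ct_up[v]) != 1 or len(ct_down[v]) != 1 for v in range(n)),
        dtype=bool, count=n,
    )
    crit = np.nonzero(is_critical)[0]
    vertex_node = {int(v): i for i, v in enumerate(crit)}
    nodes = []
    up_deg = np.zeros(crit.size, dtype=np.int64)
    down_deg = np.zeros(crit.size, dtype=np.int64)
    for i, v in enumerate(crit):
        v = int(v)
        nu, nd = len(ct_up[v]), len(ct_down[v])
        if nu + nd == 1:
            kind = "maximum" if nd == 1 else "minimum"
        else:
            kind = "saddle"
        nodes.append(CriticalNode(id=i, vertex_index=v, value=float(flat[v]),
                                  kind=kind))
    arcs: list[_Arc] = []
    vertex_arc = np.full(n, -1, dtype=np.int64)
    for v in crit:
        v = int(v)
        for w0 in ct_down[v]:
            interior = []
            w = int(w0)
            while not is_critical[w]:
                interior.append(w)
                w = int(ct_down[w][0])
            aid = len(arcs)
            top, bot = vertex_node[v], vertex_node[w]
            arr = np.asarray(interior, dtype=np.int64)
            arcs.append(_Arc(id=aid, top_node=top, bottom_node=bot, interior=arr))
            vertex_arc[arr] = aid
            up_deg[bot] += 1
            down_deg[top] += 1
    return ContourTree(field=field, nodes=nodes, arcs=arcs,
                       vertex_arc=vertex_arc, vertex_node=vertex_node,
                       up_degree=up_deg, down_degree=down_deg)


DUAL_CONNECTIVITY = {6: 26, 26: 6}


def build_contour_tree(field: ScalarField, connectivity: int = 6) -> ContourTree:
    """Join tree + split tree + combine, with dual connectivity.

    ``connectivity`` is used for the superlevel (join) side; the sublevel
    (split) side uses the dual neighborhood (6 <-> 26).  See module notes.
    """
    join = build_merge_tree(field, "ascending", connectivity)
    split = build_merge_tree(field, "descending", DUAL_CONNECTIVITY[connectivity])
    return combine_trees(join, split)


# ---------------------------------------------------------------------------
# Branch decomposition


@dataclass
class Branch:
    """Monotone extremum-to-saddle path of the contour tree.

    ``arc_path`` lists node ids from the branch's extremum to its attaching
    saddle (for the root branch: global top to global bottom).  ``voxel_count``
    and ``scalar_sum`` cover the grid vertices this branch indexes.
    """

    id: int
    top_node_id: int
    bottom_node_id: int
    parent_id: int | None
    child_ids: list[int]
    arc_path: list[int]
    extremum_node_id: int
    saddle_node_id: int | None
    voxel_count: int = 0
    scalar_sum: float = 0.0


@dataclass
class BranchDecomposition:
    field: ScalarField
    nodes: list[CriticalNode]
    branches: list[Branch]
    vertex_branch: np.ndarray  # (n,) grid vertex -> branch id
    measure: str

    @property
    def root(self) -> Branch:
        return next(b for b in self.branches if b.parent_id is None)

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def branch_ids(self) -> list[int]:
        return [b.id for b in self.branches]

    def get(self, branch_id: int) -> Branch:
        return self._index()[branch_id]

    def _index(self) -> dict[int, Branch]:
        return {b.id: b for b in self.branches}

    def depth(self, branch_id: int) -> int:
        idx = self._index()
        d, b = 0, idx[branch_id]
        while b.parent_id is not None:
            b = idx[b.parent_id]
            d += 1
        return d

    def depths(self) -> dict[int, int]:
        idx = self._index()
        out: dict[int, int] = {}

        def _d(bid: int) -> int:
            if bid in out:
                return out[bid]
            p = idx[bid].parent_id
            out[bid] = 0 if p is None else _d(p) + 1
            return out[bid]

        for b in self.branches:
            _d(b.id)
        return out

    def node_value(self, node_id: int) -> float:
        return self.nodes[node_id].value

    def persistence(self, branch_id: int) -> float:
        b = self.get(branch_id)
        return abs(self.node_value(b.top_node_id) - self.node_value(b.bottom_node_id))

    def to_dict(self) -> dict:
        vals = {nd.id: nd.value for nd in self.nodes}
        return {
            "dims": list(self.field.dims),
            "measure": self.measure,
            "nodes": [
                {"id": nd.id, "vertex_index": int(nd.vertex_index),
                 "value": nd.value, "kind": nd.kind}
                for nd in self.nodes
            ],
            "branches": [
                {
                    "id": b.id,
                    "top_node_id": b.top_node_id,
                    "bottom_node_id": b.bottom_node_id,
                    "parent_id": b.parent_id,
                    "child_ids": list(b.child_ids),
                    "arc_path": list(b.arc_path),
                    "value_span": sorted([vals[b.top_node_id], vals[b.bottom_node_id]]),
                    "voxel_count": int(b.voxel_count),
                }
                for b in self.branches
            ],
        }


@dataclass
class SegmentationMap:
    """Per-voxel branch labels; a partition of the volume."""

    labels: np.ndarray  # (nx, ny, nz) int
    branch_ids: list[int]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def region_size(self, branch_id: int) -> int:
        return int(np.count_nonzero(self.labels == branch_id))


class _CurArc:
    """Working arc during greedy leaf pruning; grows as regularized saddles
    merge their two incident arcs."""

    __slots__ = ("top", "bottom", "path", "count", "total", "vertices")

    def __init__(self, top: int, bottom: int, path: list[int],
                 count: int, total: float, vertices: list[np.ndarray]):
        self.top = top
        self.bottom = bottom
        self.path = path
        self.count = count
        self.total = total
        self.vertices = vertices


def decompose_branches(ct: ContourTree, measure: str = "persistence") -> BranchDecomposition:
    """Greedy branch decomposition: repeatedly prune the leaf arc with the
    smallest importance, so surviving (parent) branches are the
    highest-measure monotone paths.
    """
    if measure not in IMPORTANCE_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {IMPORTANCE_MEASURES}")
    if ct.n_nodes == 0:
        raise ValueError("empty contour tree")
    field = ct.field
    flat = field.flat()
    voxvol = field.voxel_volume
    values = np.array([nd.value for nd in ct.nodes])

    if ct.n_nodes == 1:
        # degenerate constant field: one root branch holding every voxel
        b = Branch(id=0, top_node_id=0, bottom_node_id=0, parent_id=None,
                   child_ids=[], arc_path=[0], extremum_node_id=0,
                   saddle_node_id=None, voxel_count=field.n_vertices,
                   scalar_sum=float(flat.sum()))
        return BranchDecomposition(
            field=field, nodes=list(ct.nodes), branches=[b],
            vertex_branch=np.zeros(field.n_vertices, dtype=np.int64),
            measure=measure)

    # working arcs with per-node incidence
    arcs: dict[int, _CurArc] = {}
    up_arcs: dict[int, set[int]] = {nd.id: set() for nd in ct.nodes}
    down_arcs: dict[int, set[int]] = {nd.id: set() for nd in ct.nodes}
    for a in ct.arcs:
        vert = [a.interior]
        cnt = int(a.interior.size)
        tot = float(flat[a.interior].sum()) if cnt else 0.0
        arcs[a.id] = _CurArc(a.top_node, a.bottom_node, [a.top_node, a.bottom_node],
                             cnt, tot, vert)
        down_arcs[a.top_node].add(a.id)
        up_arcs[a.bottom_node].add(a.id)

    def degree(node: int) -> int:
        return len(up_arcs[node]) + len(down_arcs[node])

    # fold leaf extrema vertices into their single arc
    for nd in ct.nodes:
        if degree(nd.id) == 1:
            aid = next(iter(up_arcs[nd.id] | down_arcs[nd.id]))
            arcs[aid].count += 1
            arcs[aid].total += float(flat[nd.vertex_index])
            arcs[aid].vertices.append(
                np.asarray([nd.vertex_index], dtype=np.int64))

    def arc_measure(a: _CurArc, norms: tuple[float, float, float] | None) -> float:
        p = abs(values[a.top] - values[a.bottom])
        if measure == "persistence":
            return p
        if measure == "volume":
            return float(a.count)
        if measure == "hypervolume":
            return a.total * voxvol
        pmax, vmax, hmax = norms  # type: ignore[misc]
        ph = p / pmax if pmax > 0 else 0.0
        vh = a.count / vmax if vmax > 0 else 0.0
        hh = (a.total * voxvol) / hmax if hmax > 0 else 0.0
        return (np.sqrt(3.0) / 4.0) * (ph * vh + vh * hh + hh * ph)

    # the global extremum pair is reserved for the root branch: their leaf
    # arcs are never pruned (ties broken by vertex index, as in the sweep)
    ext_key = {nd.id: (nd.value, nd.vertex_index) for nd in ct.nodes}
    global_max = max(ext_key, key=ext_key.get)
    global_min = min(ext_key, key=ext_key.get)

    pruned: list[dict] = []  # records of pruned branches, in prune order
    next_arc_id = max(arcs.keys()) + 1
    while len(arcs) > 1:
        norms = None
        if measure == "triangle_area":
            norms = (
                max(abs(values[a.top] - values[a.bottom]) for a in arcs.values()),
                max(float(a.count) for a in arcs.values()),
                max(a.total * voxvol for a in arcs.values()),
            )
        best = None
        fallback = None
        for aid, a in arcs.items():
            top_leaf = degree(a.top) == 1
            bot_leaf = degree(a.bottom) == 1
            if not (top_leaf or bot_leaf):
                continue
            if top_leaf and bot_leaf:
                continue  # would be the final root arc
            # the saddle must keep an arc on the pruned side, otherwise the
            # remaining path through it would lose monotonicity
            if top_leaf:
                if len(up_arcs[a.bottom]) < 2:
                    continue
                leaf = a.top
            else:
                if len(down_arcs[a.top]) < 2:
                    continue
                leaf = a.bottom
            m = arc_measure(a, norms)
            key = (m, aid)
            if leaf in (global_max, global_min):
                if fallback is None or key < fallback[0]:
                    fallback = (key, aid, leaf)
                continue
            if best is None or key < best[0]:
                best = (key, aid, leaf)
        if best is None:
            best = fallback  # degenerate trees where an extreme arc must go
        assert best is not None, "no prunable leaf arc found"
        _, aid, leaf = best
        a = arcs.pop(aid)
        saddle = a.bottom if leaf == a.top else a.top
        path = a.path if leaf == a.top else list(reversed(a.path))
        pruned.append({
            "extremum": leaf, "saddle": saddle, "path": path,
            "count": a.count, "total": a.total, "vertices": a.vertices,
        })
        up_arcs[saddle].discard(aid)
        down_arcs[saddle].discard(aid)
        up_arcs[leaf].discard(aid)
        down_arcs[leaf].discard(aid)
        # regularized saddle: splice its two remaining arcs into one
        if len(up_arcs[saddle]) == 1 and len(down_arcs[saddle]) == 1:
            ua_id = next(iter(up_arcs[saddle]))
            da_id = next(iter(down_arcs[saddle]))
            ua = arcs.pop(ua_id)
            da = arcs.pop(da_id)
            up_arcs[saddle].clear()
            down_arcs[saddle].clear()
            merged = _CurArc(
                ua.top, da.bottom,
                ua.path + da.path[1:],
                ua.count + da.count + 1,
                ua.total + da.total + float(values[saddle]),
                ua.vertices + da.vertices
                + [np.asarray([ct.nodes[saddle].vertex_index], dtype=np.int64)],
            )
            new_id = next_arc_id
            next_arc_id += 1
            arcs[new_id] = merged
            down_arcs[ua.top].discard(ua_id)
            down_arcs[ua.top].add(new_id)
            up_arcs[da.bottom].discard(da_id)
            up_arcs[da.bottom].add(new_id)

    # the survivor is the root branch
    root_arc = next(iter(arcs.values()))
    branches_raw = pruned + [{
        "extremum": root_arc.top, "saddle": None, "path": root_arc.path,
        "count": root_arc.count, "total": root_arc.total,
        "vertices": root_arc.vertices,
    }]

    # node ownership: a node belongs to the branch whose path traverses it
    owner: dict[int, int] = {}
    for i, rec in enumerate(branches_raw):
        path = rec["path"] if rec["saddle"] is None else rec["path"][:-1]
        for node in path:
            owner.setdefault(node, i)
    parent_raw = [
        None if rec["saddle"] is None else owner[rec["saddle"]]
        for rec in branches_raw
    ]

    # relabel breadth-first from the root so ids are stable and root == 0
    root_raw = len(branches_raw) - 1
    children_raw: dict[int, list[int]] = {i: [] for i in range(len(branches_raw))}
    for i, p in enumerate(parent_raw):
        if p is not None:
            children_raw[p].append(i)
    relabel: dict[int, int] = {}
    order = deque([root_raw])
    while order:
        i = order.popleft()
        relabel[i] = len(relabel)
        for c in sorted(children_raw[i]):
            order.append(c)

    branches: list[Branch] = [None] * len(branches_raw)  # type: ignore[list-item]
    vertex_branch = np.full(field.n_vertices, -1, dtype=np.int64)
    for i, rec in enumerate(branches_raw):
        bid = relabel[i]
        path = rec["path"]
        top, bot = path[0], path[-1]
        if values[top] < values[bot]:
            top, bot = bot, top
        br = Branch(
            id=bid, top_node_id=int(top), bottom_node_id=int(bot),
            parent_id=None if parent_raw[i] is None else relabel[parent_raw[i]],
            child_ids=sorted(relabel[c] for c in children_raw[i]),
            arc_path=[int(x) for x in path],
            extremum_node_id=int(rec["extremum"]),
            saddle_node_id=None if rec["saddle"] is None else int(rec["saddle"]),
            voxel_count=int(rec["count"]), scalar_sum=float(rec["total"]),
        )
        branches[bid] = br
        for chunk in rec["vertices"]:
            vertex_branch[chunk] = bid
    # degenerate multi-saddles may never regularize into a spliced arc; give
    # their voxel to the branch whose path owns the node
    for nd in ct.nodes:
        v = int(nd.vertex_index)
        if vertex_branch[v] < 0:
            bid = relabel[owner[nd.id]]
            vertex_branch[v] = bid
            branches[bid].voxel_count += 1
            branches[bid].scalar_sum += float(flat[v])
    assert int((vertex_branch >= 0).sum()) == field.n_vertices
    return BranchDecomposition(field=field, nodes=list(ct.nodes),
                               branches=branches, vertex_branch=vertex_branch,
                               measure=measure)


def _branch_measure(bd: BranchDecomposition, b: Branch, measure: str,
                    norms: tuple[float, float, float] | None) -> float:
    p = bd.persistence(b.id)
    if measure == "persistence":
        return p
    if measure == "volume":
        return float(b.voxel_count)
    if measure == "hypervolume":
        return b.scalar_sum * bd.field.voxel_volume
    pmax, vmax, hmax = norms  # type: ignore[misc]
    ph = p / pmax if pmax > 0 else 0.0
    vh = b.voxel_count / vmax if vmax > 0 else 0.0
    hh = (b.scalar_sum * bd.field.voxel_volume) / hmax if hmax > 0 else 0.0
    return (np.sqrt(3.0) / 4.0) * (ph * vh + vh * hh + hh * ph)


def simplify_tree(
    bd: BranchDecomposition,
    measure: str = "persistence",
    threshold: float | None = None,
    target_branch_count: int | None = None,
) -> BranchDecomposition:
    """Iteratively prune childless leaf branches, smallest measure first.

    Either remove every leaf branch whose measure falls below ``threshold``
    (re-examining parents as they become leaves), or prune until exactly
    ``target_branch_count`` branches remain.  The root branch is never
    removed; pruned branches donate their voxels to their parent.
    """
    if measure not in IMPORTANCE_MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    if (threshold is None) == (target_branch_count is None):
        raise ValueError("specify exactly one of threshold / target_branch_count")
    if threshold is not None and threshold < 0:
        raise ValueError("threshold must be >= 0")
    if target_branch_count is not None:
        if target_branch_count < 1:
            raise ValueError("target_branch_count must be >= 1")
        if target_branch_count > bd.n_branches:
            warnings.warn(
                f"target_branch_count={target_branch_count} exceeds current "
                f"branch count {bd.n_branches}; returning input unchanged",
                stacklevel=2)
            return bd

    import copy

    out = BranchDecomposition(
        field=bd.field, nodes=bd.nodes,
        branches=copy.deepcopy(bd.branches),
        vertex_branch=bd.vertex_branch.copy(), measure=bd.measure)

    def removable() -> list[Branch]:
        return [b for b in out.branches if not b.child_ids and b.parent_id is not None]

    while True:
        cands = removable()
        if not cands:
            break
        norms = None
        if measure == "triangle_area":
            norms = (
                max(out.persistence(b.id) for b in out.branches),
                max(float(b.voxel_count) for b in out.branches),
                max(b.scalar_sum * out.field.voxel_volume for b in out.branches),
            )
        scored = sorted(((_branch_measure(out, b, measure, norms), b.id, b)
                         for b in cands))
        m, _, victim = scored[0]
        if threshold is not None:
            if m >= threshold:
                break
        else:
            if out.n_branches <= target_branch_count:  # type: ignore[operator]
                break
        parent = out.get(victim.parent_id)  # type: ignore[arg-type]
        parent.child_ids.remove(victim.id)
        parent.voxel_count += victim.voxel_count
        parent.scalar_sum += victim.scalar_sum
        out.vertex_branch[out.vertex_branch == victim.id] = parent.id
        out.branches.remove(victim)
    return out


def segment_field(field: ScalarField, bd: BranchDecomposition) -> SegmentationMap:
    """Label every voxel with the branch that indexes it.

    A voxel belongs to the most specific branch whose value span covers it
    within the voxel's superlevel/sublevel component; the labels were recorded
    while replaying the union-find sweep, so this is a lookup.
    """
    if bd.field is not field and not (
        bd.field.dims == field.dims
        and np.array_equal(bd.field.values, field.values)
    ):
        raise ValueError("decomposition was not derived from this field")
    labels = bd.vertex_branch.reshape(field.dims, order="F")
    return SegmentationMap(labels=labels, branch_ids=bd.branch_ids)
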