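"""Per-branch topological attributes that drive illumination.

Each branch of the decomposition is annotated with persistence (scalar span
of its critical pair), volume (voxel count of its indexed region),
hypervolume (Riemann sum of the field over that region times the voxel
volume), topological depth, sibling/child counts, attaching saddle value, an
importance-triangle area combining the three importance measures, and a
topological saliency expressing importance relative to branches at nearby
depths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contour_tree import BranchDecomposition, SegmentationMap
from .field import ScalarField

__all__ = [
    "BranchAttributes",
    "SaliencyParams",
    "annotate_structure",
    "importance_triangle_area",
    "topological_saliency",
    "attributes_to_frame",
]

#: maximum of the importance-triangle area, attained at (1, 1, 1)
TRIANGLE_AREA_MAX = 3.0 * math.sqrt(3.0) / 4.0


@dataclass
class BranchAttributes:
    branch_id: int
    persistence: float
    volume: int
    hypervolume: float
    depth: int
    n_siblings: int
    n_children: int
    saddle_value: float
    triangle_area: float = 0.0
    saliency: float = 0.0
    empty: bool = False  # zero-voxel branch, flagged but allowed


@dataclass
class SaliencyParams:
    """Configuration of the depth-weighted saliency.

    ``measure`` is the topological feature t (persistence or volume);
    ``radius`` is the Gaussian neighborhood radius r, by default the maximum
    topological depth of the tree (>= 1 so a flat tree stays well defined,
    where all depth distances are 0 and saliency reduces to t_i / sum t_j).
    """

    measure: str = "persistence"
    radius: float | None = None


def importance_triangle_area(p: float, v: float, hv: float) -> float:
    """Area of the importance triangle for normalized (p, v, hv).

    The three measures are laid out radially along coplanar axes 120 degrees
    apart; the triangle through the three points has area
    (sqrt(3)/4) * (p*v + v*hv + hv*p).  Zero iff at least two inputs are
    zero; symmetric; monotone in each coordinate.
    """
    for name, x in (("p", p), ("v", v), ("hv", hv)):
        if not (0.0 <= x <= 1.0):
            raise ValueError(f"normalized {name} must lie in [0,1], got {x}")
    return (math.sqrt(3.0) / 4.0) * (p * v + v * hv + hv * p)


def topological_saliency(
    attrs: dict[int, BranchAttributes], params: SaliencyParams | None = None
) -> dict[int, float]:
    """Depth-weighted relative importance S_i in (0, 1] per branch.

    S_i = t_i / sum_j w_ij t_j with Gaussian weights
    w_ij = exp(-d(i,j)^2 / r^2) where d is the topological-depth difference
    and r the neighborhood radius (max depth by default).  Scale-invariant in
    t; equals 1 for a single branch.
    """
    params = params or SaliencyParams()
    if params.measure not in ("persistence", "volume"):
        raise ValueError("saliency measure must be 'persistence' or 'volume'")
    ids = sorted(attrs)
    t = np.array([
        attrs[i].persistence if params.measure == "persistence" else attrs[i].volume
        for i in ids
    ], dtype=float)
    if not np.any(t > 0):
        raise ValueError("all branch measures are zero; saliency undefined")
    depth = np.array([attrs[i].depth for i in ids], dtype=float)
    r = params.radius if params.radius is not None else max(depth.max(), 1.0)
    if r <= 0:
        raise ValueError("saliency radius must be positive")
    d2 = (depth[:, None] - depth[None, :]) ** 2
    w = np.exp(-d2 / r**2)
    denom = w @ t
    sal = np.where(denom > 0, t / denom, 0.0)
    # zero-measure branches carry no saliency mass but stay positive-bounded
    sal = np.clip(sal, 0.0, 1.0)
    return {i: float(s) for i, s in zip(ids, sal)}


def annotate_structure(
    bd: BranchDecomposition,
    field: ScalarField,
    seg: SegmentationMap,
    saliency_params: SaliencyParams | None = None,
) -> dict[int, BranchAttributes]:
    """Compute the full attribute table for a decomposition.

    Persistence comes from the branch's critical pair, volume/hypervolume
    from the segmentation labels, depths and sibling/child counts from the
    branch hierarchy.  The importance-triangle area is normalized within each
    sibling group (each measure divided by the group's maximum); saliency is
    computed over all branches.
    """
    if seg.dims != field.dims:
        raise ValueError("segmentation/field dims mismatch")
    labels = seg.labels.ravel(order="F")
    flat = field.flat()
    nb = max(bd.branch_ids) + 1
    counts = np.bincount(labels, minlength=nb)
    sums = np.bincount(labels, weights=flat, minlength=nb)
    voxvol = field.voxel_volume
    depths = bd.depths()
    idx = {b.id: b for b in bd.branches}

    attrs: dict[int, BranchAttributes] = {}
    for b in bd.branches:
        if b.parent_id is None:
            n_sib = 0
            saddle = bd.node_value(b.bottom_node_id)
        else:
            n_sib = len(idx[b.parent_id].child_ids) - 1
            saddle = bd.node_value(b.saddle_node_id)  # type: ignore[arg-type]
        vol = int(counts[b.id])
        attrs[b.id] = BranchAttributes(
            branch_id=b.id,
            persistence=bd.persistence(b.id),
            volume=vol,
            hypervolume=float(sums[b.id]) * voxvol,
            depth=depths[b.id],
            n_siblings=n_sib,
            n_children=len(b.child_ids),
            saddle_value=float(saddle),
            empty=vol == 0,
        )

    # importance-triangle area, normalized per sibling group
    groups: dict[int | None, list[int]] = {}
    for b in bd.branches:
        groups.setdefault(b.parent_id, []).append(b.id)
    for members in groups.values():
        pmax = max(attrs[i].persistence for i in members)
        vmax = max(attrs[i].volume for i in members)
        hmax = max(attrs[i].hypervolume for i in members)
        for i in members:
            a = attrs[i]
            a.triangle_area = importance_triangle_area(
                a.persistence / pmax if pmax > 0 else 0.0,
                a.volume / vmax if vmax > 0 else 0.0,
                a.hypervolume / hmax if hmax > 0 else 0.0,
            )

    try:
        sal = topological_saliency(attrs, saliency_params)
    except ValueError:
        sal = {i: 1.0 / len(attrs) for i in attrs}  # all-zero measures
    for i, s in sal.items():
        attrs[i].saliency = s
    return attrs


def attributes_to_frame(attrs: dict[int, BranchAttributes]) -> pd.DataFrame:
    """Attribute table as a DataFrame (one row per branch), CSV-ready."""
    rows = [
        {
            "branch_id": a.branch_id,
            "persistence": a.persistence,
            "volume": a.volume,
            "hypervolume": a.hypervolume,
            "depth": a.depth,
            "n_siblings": a.n_siblings,
            "n_children": a.n_children,
            "saddle_value": a.saddle_value,
            "saliency": a.saliency,
            "triangle_area": a.triangle_area,
        }
        for a in sorted(attrs.values(), key=lambda a: a.branch_id)
    ]
    return pd.DataFrame(rows)
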