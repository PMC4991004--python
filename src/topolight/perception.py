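"""Two-phase topology-aware illumination perception contrast model.

The goal is to assign every branch a luminance such that neighboring
(parent/child) structures differ by at least one Just-Noticeable-Difference
(JND), with inner structures brighter, and to then amplify those differences
using a contrast-ratio "residue flow" down the tree.

Phase 1 (initialization): the root receives a user luminance L_0; every
child receives its parent's luminance plus the JND at the parent's adaptation
level, recursively.  Gaps are exactly one JND.

Phase 2 (optimization): breadth-first from the root.  For a parent at
luminance L with contrast ratio gamma, its children share the base luminance
L' = L / gamma, split among siblings by an importance factor f_b (the
normalized importance-triangle area of persistence, volume and hypervolume)
and a saddle factor f_d (min-max normalized saddle value).  Candidates whose
gap to the parent falls short of the JND are corrected by adding the
shortfall onto the initialization luminance; a post-hoc floor guarantees the
JND bound and that no branch falls below its initialization value.  The
contrast ratio flows down the tree losing a head-loss fraction
dh = (1/K) * Q * p / n_c per branch (hydraulic-conductivity analogue,
K = 300 for water through sand), so deeper levels get smaller gamma, i.e.
relatively brighter children.

The JND curve is the standard piecewise threshold-versus-intensity function
covering the whole human vision range (scotopic rod floor through photopic
Weber behavior); log is base 10 and luminance is in cd/m^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dcfield

import numpy as np
import pandas as pd

from .attributes import BranchAttributes, TRIANGLE_AREA_MAX
from .contour_tree import BranchDecomposition
from .illumination import LightingCoefficients, LightingTable, LtfConfig

__all__ = [
    "JND_BREAKPOINTS",
    "ContrastFlowParams",
    "LuminanceAssignment",
    "jnd_log_delta",
    "jnd_delta",
    "initialize_luminance",
    "head_loss",
    "gamma_residue",
    "parent_child_base",
    "sibling_luminance",
    "enforce_jnd",
    "optimize_luminance",
    "luminance_to_coefficients",
    "GAMMA_FLOOR",
]

#: regime breakpoints of the JND curve, in log10 cd/m^2
JND_BREAKPOINTS = (-3.94, -1.44, -0.0184, 1.9)

#: floor on the contrast ratio, keeping base luminance finite
GAMMA_FLOOR = 1e-3


def jnd_log_delta(luminance: float) -> float:
    """log10 of the JND threshold at adaptation luminance L (cd/m^2).

    Piecewise over log10(L): a scotopic floor of -2.86 below -3.94; a rod
    transition (0.405*x + 1.6)^2.18 - 2.86 up to -1.44; a mesopic linear
    regime x - 0.395 up to -0.0184; a cone transition
    (0.294*x + 0.65)^2.7 - 0.72 up to 1.9; and the photopic Weber regime
    x - 1.255 above.
    """
    if luminance <= 0:
        raise ValueError("luminance must be positive")
    x = math.log10(luminance)
    if x < -3.94:
        return -2.86
    if x < -1.44:
        return (0.405 * x + 1.6) ** 2.18 - 2.86
    if x < -0.0184:
        return x - 0.395
    if x < 1.9:
        return (0.294 * x + 0.65) ** 2.7 - 0.72
    return x - 1.255


def jnd_delta(luminance: float) -> float:
    """JND threshold Delta-L (cd/m^2) at adaptation luminance L."""
    return 10.0 ** jnd_log_delta(luminance)


@dataclass
class ContrastFlowParams:
    """Parameters of the perception model.

    L0: root luminance (cd/m^2), user-set.  gamma0: root contrast ratio in
    (0, 1).  Q: flow speed of the residue model.  K: hydraulic conductivity
    (300 for water through sand).
    """

    L0: float = 10.0
    gamma0: float = 0.8
    Q: float = 1.0
    K: float = 300.0

    def __post_init__(self) -> None:
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if not (0.0 < self.gamma0 <= 1.0):
            raise ValueError("gamma0 must lie in (0,1]")
        if self.Q <= 0 or self.K <= 0:
            raise ValueError("Q and K must be positive")


@dataclass
class LuminanceAssignment:
    luminance: dict[int, float]
    init_luminance: dict[int, float]
    delta_vs_parent: dict[int, float]
    gamma: dict[int, float]
    corrections: list[int] = _dcfield(default_factory=list)  # branches needing Eq-style JND correction
    diagnostics: list[dict] = _dcfield(default_factory=list)

    def diagnostics_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.diagnostics)


def initialize_luminance(bd: BranchDecomposition, L0: float) -> dict[int, float]:
    """Phase-1 luminance: root L0; each child its parent plus one JND."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    lum: dict[int, float] = {}
    order = _bfs_order(bd)
    idx = {b.id: b for b in bd.branches}
    for bid in order:
        parent = idx[bid].parent_id
        if parent is None:
            lum[bid] = float(L0)
        else:
            lum[bid] = lum[parent] + jnd_delta(lum[parent])
    return lum


def head_loss(p_norm: float, n_children: int, Q: float, K: float) -> float:
    """dh = (1/K) * (Q * p / n_c), clamped to [0, 1].

    p is the branch persistence normalized to [0, 1] over the tree; the flow
    divides among the branch's children, so more children means less loss
    per level.  Not applicable to leaves (no flow to children).
    """
    if n_children < 1:
        raise ValueError("head loss applies to branches with children")
    if Q <= 0 or K <= 0:
        raise ValueError("Q and K must be positive")
    if p_norm < 0:
        raise ValueError("persistence must be >= 0")
    return float(np.clip((Q * p_norm / n_children) / K, 0.0, 1.0))


def gamma_residue(gamma_prev: float, dh: float) -> float:
    """gamma_i = (1 - dh) * gamma_{i-1}, floored at GAMMA_FLOOR."""
    if not (0.0 < gamma_prev <= 1.0):
        raise ValueError("gamma_prev must lie in (0,1]")
    if not (0.0 <= dh <= 1.0):
        raise ValueError("head loss must lie in [0,1]")
    return max((1.0 - dh) * gamma_prev, GAMMA_FLOOR)


def parent_child_base(L_prev: float, gamma_prev: float) -> float:
    """Base luminance for the next level: L' = L_prev / gamma_prev >= L_prev."""
    if gamma_prev <= 0:
        raise ValueError("gamma must be positive")
    return L_prev / gamma_prev


def sibling_luminance(
    base: float, siblings: list[BranchAttributes]
) -> dict[int, float]:
    """Split a level's base luminance among siblings.

    L_ij = base * f_b * f_d where f_b is the sibling's importance-triangle
    area normalized to [0, 1] by its maximum possible value, and
    f_d = (s_ij - s_min) / (s_max - s_min) ranks siblings by saddle value
    (larger saddle value, i.e. more deeply attached, gets more light).  A
    singleton group has no intra-level ranking to express: f_d = 1.
    """
    if not siblings:
        raise ValueError("empty sibling group")
    saddles = [a.saddle_value for a in siblings]
    smin, smax = min(saddles), max(saddles)
    ds = smax - smin
    out: dict[int, float] = {}
    for a in siblings:
        f_b = a.triangle_area / TRIANGLE_AREA_MAX
        f_d = 1.0 if ds == 0 else (a.saddle_value - smin) / ds
        out[a.branch_id] = base * f_b * f_d
    return out


def enforce_jnd(
    candidate: float, L_parent: float, L_init: float
) -> tuple[float, bool]:
    """Guarantee the child exceeds its parent by at least one JND.

    If the candidate's gap to the parent is already >= JND(L_parent) it is
    kept.  Otherwise the shortfall |dL - JND| is added onto the
    initialization luminance; the correction is applied at most twice, then
    a floor of max(L_init, L_parent + JND) enforces both the perceptibility
    bound and that no branch ends below its initialization value.

    Returns (final luminance, whether a correction was needed).
    """
    jnd = jnd_delta(L_parent)
    dL = candidate - L_parent
    corrected = False
    L = candidate
    if dL < jnd:
        corrected = True
        L = L_init + abs(dL - jnd)
        dL2 = L - L_parent
        if dL2 < jnd:
            L = L_init + abs(dL2 - jnd)
    L = max(L, L_init, L_parent + jnd)
    return float(L), corrected


def _bfs_order(bd: BranchDecomposition) -> list[int]:
    idx = {b.id: b for b in bd.branches}
    root = bd.root.id
    order, queue = [], [root]
    while queue:
        bid = queue.pop(0)
        order.append(bid)
        queue.extend(sorted(idx[bid].child_ids))
    return order


def optimize_luminance(
    bd: BranchDecomposition,
    attrs: dict[int, BranchAttributes],
    flow: ContrastFlowParams | None = None,
) -> LuminanceAssignment:
    """Phase-2 optimization: JND floor plus residue-flow contrast.

    Deterministic breadth-first pass from the root; per parent the children
    share the base luminance L_parent / gamma_parent, split by importance and
    saddle rank, then JND-enforced.  gamma decreases down the tree by the
    per-branch head loss, so inner levels get relatively more light.
    """
    flow = flow or ContrastFlowParams()
    init = initialize_luminance(bd, flow.L0)
    idx = {b.id: b for b in bd.branches}
    root = bd.root.id
    pmax = max((attrs[i].persistence for i in attrs), default=0.0)

    lum: dict[int, float] = {root: flow.L0}
    gamma: dict[int, float] = {root: flow.gamma0}
    delta: dict[int, float] = {root: 0.0}
    corrections: list[int] = []
    diagnostics: list[dict] = []

    for bid in _bfs_order(bd):
        b = idx[bid]
        if not b.child_ids:
            continue
        base = parent_child_base(lum[bid], gamma[bid])
        sibs = [attrs[c] for c in sorted(b.child_ids)]
        cand = sibling_luminance(base, sibs)
        jnd_here = jnd_delta(lum[bid])
        for c in sorted(b.child_ids):
            final, corrected = enforce_jnd(cand[c], lum[bid], init[c])
            lum[c] = final
            delta[c] = final - lum[bid]
            if corrected:
                corrections.append(c)
            p_norm = attrs[c].persistence / pmax if pmax > 0 else 0.0
            nc = len(idx[c].child_ids)
            dh = head_loss(p_norm, nc, flow.Q, flow.K) if nc >= 1 else 0.0
            gamma[c] = gamma_residue(gamma[bid], dh)
            diagnostics.append({
                "branch_id": c, "parent_id": bid, "depth": attrs[c].depth,
                "candidate": cand[c], "final": final, "init": init[c],
                "jnd_parent": jnd_here, "gamma": gamma[c], "head_loss": dh,
                "corrected": corrected,
            })
    return LuminanceAssignment(
        luminance=lum, init_luminance=init, delta_vs_parent=delta,
        gamma=gamma, corrections=corrections, diagnostics=diagnostics)


def luminance_to_coefficients(
    la: LuminanceAssignment, cfg: LtfConfig
) -> LightingTable:
    """Map branch luminances to diffuse coefficients.

    Luminance drives the diffuse term (the most instinctive reflection of an
    object): k_d = w * L / max L, so the brightest branch gets k_d = w and
    the ranking by k_d equals the ranking by luminance.  k_a, k_s and the
    shininess are shared.
    """
    if not la.luminance:
        raise ValueError("empty luminance assignment")
    lmax = max(la.luminance.values())
    if lmax <= 0:
        raise ValueError("luminances must be positive")
    return {
        i: LightingCoefficients(
            k_a=cfg.k_a,
            k_d=float(np.clip(cfg.weight * L / lmax, 0.0, 1.0)),
            k_s=cfg.k_s,
            shininess=cfg.shininess,
            f_att=1.0,
        )
        for i, L in la.luminance.items()
    }
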