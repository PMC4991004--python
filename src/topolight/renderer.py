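"""CPU ray-casting volume renderer with branch-indexed lighting.

Orthographic (default) or perspective rays are marched front to back
through the volume; each sample interpolates the scalar field trilinearly,
looks up its branch label with nearest-neighbor sampling (labels are
categorical), fetches that branch's transfer-function color/opacity and
lighting coefficients, shades with attenuated Blinn-Phong, and composites
with early termination.  Opacity is corrected for the step size:
a' = 1 - (1 - a)^(step / reference_step).
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield
import colorsys

import numpy as np
from scipy import ndimage

from .contour_tree import BranchDecomposition, SegmentationMap
from .field import ScalarField
from .illumination import LightingTable

__all__ = [
    "TransferFunction",
    "RenderConfig",
    "gradient_normals",
    "raycast_image",
    "branch_pixel_masks",
    "default_transfer_function",
]


@dataclass
class TransferFunction:
    """Per-branch constant color and opacity (a deliberately simple
    stand-in for a full topology-controlled transfer-function generator)."""

    color: dict[int, tuple[float, float, float]]
    opacity: dict[int, float]

    def __post_init__(self) -> None:
        for i, a in self.opacity.items():
            if not (0.0 <= a <= 1.0):
                raise ValueError(f"opacity for branch {i} outside [0,1]")

    def to_dict(self) -> dict:
        return {
            str(i): {"rgb": list(self.color[i]), "opacity": self.opacity[i]}
            for i in sorted(self.color)
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "TransferFunction":
        return cls(
            color={int(i): tuple(d["rgb"]) for i, d in raw.items()},
            opacity={int(i): float(d["opacity"]) for i, d in raw.items()},
        )


def default_transfer_function(bd: BranchDecomposition,
                              opacity: float = 0.12) -> TransferFunction:
    """Distinct hues per branch (deeper branches more saturated/opaque)."""
    depths = bd.depths()
    dmax = max(depths.values()) or 1
    color, alpha = {}, {}
    for k, b in enumerate(sorted(bd.branches, key=lambda b: b.id)):
        hue = (k * 0.381966) % 1.0  # golden-ratio spacing
        d = depths[b.id] / dmax
        color[b.id] = tuple(colorsys.hsv_to_rgb(hue, 0.55 + 0.45 * d, 0.95))
        alpha[b.id] = min(1.0, opacity * (1.0 + d))
    return TransferFunction(color=color, opacity=alpha)


@dataclass
class RenderConfig:
    image_size: tuple[int, int] = (64, 64)  # (width, height)
    camera_pos: tuple[float, float, float] | None = None
    look_at: tuple[float, float, float] | None = None
    up: tuple[float, float, float] = (0.0, 0.0, 1.0)
    orthographic: bool = True
    ortho_height: float | None = None  # world units; default fits the volume
    step: float = 0.5  # in units of the smallest voxel spacing
    reference_step: float = 1.0
    light_dir: tuple[float, float, float] | None = None  # toward the light
    background: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.step <= 0 or self.reference_step <= 0:
            raise ValueError("step sizes must be positive")
        w, h = self.image_size
        if w < 1 or h < 1:
            raise ValueError("image dims must be positive")


def gradient_normals(field: ScalarField, eps: float = 1e-8) -> np.ndarray:
    """Central-difference gradient, normalized per voxel.

    Returns an (nx, ny, nz, 3) array; voxels whose gradient magnitude falls
    below ``eps`` get a zero normal (shaded ambient-only downstream).
    """
    gx, gy, gz = np.gradient(field.values, *field.spacing)
    g = np.stack([gx, gy, gz], axis=-1)
    norm = np.linalg.norm(g, axis=-1, keepdims=True)
    out = np.where(norm > eps, g / np.where(norm > 0, norm, 1.0), 0.0)
    return out


def _camera_basis(cfg: RenderConfig, dims, spacing):
    extent = np.array(dims, float) * np.array(spacing, float)
    center = extent / 2.0
    look_at = np.array(cfg.look_at, float) if cfg.look_at is not None else center
    if cfg.camera_pos is not None:
        pos = np.array(cfg.camera_pos, float)
    else:
        pos = center + np.array([0.0, -2.0 * extent.max(), 0.0])
    forward = look_at - pos
    fn = np.linalg.norm(forward)
    if fn == 0:
        raise ValueError("camera position coincides with look-at point")
    forward = forward / fn
    up = np.array(cfg.up, float)
    right = np.cross(forward, up)
    rn = np.linalg.norm(right)
    if rn < 1e-12:  # up parallel to view direction
        up = np.array([0.0, 1.0, 0.0])
        right = np.cross(forward, up)
        rn = np.linalg.norm(right)
    right /= rn
    true_up = np.cross(right, forward)
    return pos, forward, right, true_up, extent


def _lookup_tables(table: LightingTable, tf: TransferFunction):
    nb = max(table) + 1
    ka = np.zeros(nb); kd = np.zeros(nb); ks = np.zeros(nb)
    shin = np.ones(nb); fatt = np.ones(nb)
    col = np.zeros((nb, 3)); alp = np.zeros(nb)
    for i, c in table.items():
        ka[i], kd[i], ks[i] = c.k_a, c.k_d, c.k_s
        shin[i], fatt[i] = c.shininess, c.f_att
    for i, rgb in tf.color.items():
        if i < nb:
            col[i] = rgb
            alp[i] = tf.opacity[i]
    return ka, kd, ks, shin, fatt, col, alp


def raycast_image(
    field: ScalarField,
    seg: SegmentationMap,
    table: LightingTable,
    tf: TransferFunction,
    cfg: RenderConfig,
) -> np.ndarray:
    """Front-to-back composited image, shape (height, width, 3) in [0, 1].

    Deterministic: identical inputs produce bit-identical images.
    """
    if seg.dims != field.dims:
        raise ValueError("segmentation/field dims mismatch")
    missing = set(np.unique(seg.labels)) - set(table)
    if missing:
        raise ValueError(f"lighting table missing branches {sorted(missing)}")

    dims = field.dims
    spacing = np.array(field.spacing, float)
    pos, forward, right, true_up, extent = _camera_basis(cfg, dims, spacing)
    W, H = cfg.image_size
    oh = cfg.ortho_height if cfg.ortho_height is not None else 1.1 * float(extent.max())
    ow = oh * W / H

    u = (np.arange(W) + 0.5) / W - 0.5
    v = 0.5 - (np.arange(H) + 0.5) / H
    UU, VV = np.meshgrid(u * ow, v * oh)  # (H, W)
    if cfg.orthographic:
        origins = (pos[None, None, :] + UU[..., None] * right[None, None, :]
                   + VV[..., None] * true_up[None, None, :])
        dirs = np.broadcast_to(forward, origins.shape)
    else:
        focal = 1.5 * oh
        targets = (pos + focal * forward)[None, None, :] \
            + UU[..., None] * right + VV[..., None] * true_up
        dirs = targets - pos[None, None, :]
        dirs = dirs / np.linalg.norm(dirs, axis=-1, keepdims=True)
        origins = np.broadcast_to(pos, dirs.shape)

    origins = origins.reshape(-1, 3)
    dirs = dirs.reshape(-1, 3)
    npix = origins.shape[0]

    # slab intersection with the volume AABB (voxel centers 0..dims-1)
    lo = np.zeros(3)
    hi = (np.array(dims, float) - 1.0) * spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo[None, :] - origins) / dirs
        t1 = (hi[None, :] - origins) / dirs
    tmin = np.nanmax(np.where(np.isfinite(t0) | np.isfinite(t1),
                              np.minimum(t0, t1), -np.inf), axis=1)
    tmax = np.nanmin(np.where(np.isfinite(t0) | np.isfinite(t1),
                              np.maximum(t0, t1), np.inf), axis=1)
    tmin = np.maximum(tmin, 0.0)

    step = cfg.step * float(spacing.min())
    ka, kd, ks, shin, fatt, col, alp = _lookup_tables(table, tf)
    normals = gradient_normals(field)

    light = np.array(cfg.light_dir, float) if cfg.light_dir is not None else -forward
    light = light / np.linalg.norm(light)
    view = -forward

    color_acc = np.zeros((npix, 3))
    trans = np.ones(npix)
    hit = tmax > tmin
    t = np.where(hit, tmin, np.inf)
    t_global_max = float(np.max(tmax[hit])) if np.any(hit) else 0.0

    labels = seg.labels
    tcur = t.copy()
    while True:
        active = (tcur <= tmax) & (trans > 0.01) & np.isfinite(tcur)
        if not np.any(active):
            break
        p = origins[active] + tcur[active, None] * dirs[active]
        voxel = p / spacing[None, :]
        coords = voxel.T  # (3, m) in voxel index space
        inside = np.all((coords >= 0) & (coords <= (np.array(dims)[:, None] - 1)), axis=0)
        if np.any(inside):
            ci = coords[:, inside]
            val_label = labels[tuple(np.round(ci).astype(int))]
            nrm = np.stack([
                ndimage.map_coordinates(normals[..., k], ci, order=1, mode="nearest")
                for k in range(3)
            ], axis=-1)
            nn = np.linalg.norm(nrm, axis=-1, keepdims=True)
            nrm = np.where(nn > 1e-6, nrm / np.where(nn > 0, nn, 1.0), 0.0)

            # two-sided lighting: the gradient's sign depends on whether the
            # structure is a maximum or a minimum, so |N.L| is used (then
            # clamped), the standard choice for gradient-shaded DVR
            ndl = np.clip(np.abs(nrm @ light), 0.0, 1.0)
            half = light + view
            half = half / np.linalg.norm(half)
            ndh = np.clip(np.abs(nrm @ half), 0.0, 1.0)
            flat = np.linalg.norm(nrm, axis=-1) < 1e-6
            ndl = np.where(flat, 0.0, ndl)
            ndh = np.where(flat, 0.0, ndh)

            b = val_label
            shade = (ka[b, None] + (kd[b] * fatt[b] * ndl)[:, None]) * col[b]
            shade = shade + ((ks[b] * fatt[b]) * ndh ** shin[b])[:, None]
            shade = np.clip(shade, 0.0, 1.0)
            a = alp[b]
            a_corr = 1.0 - (1.0 - a) ** (step / cfg.reference_step)

            idx = np.nonzero(active)[0][inside]
            color_acc[idx] += (trans[idx] * a_corr)[:, None] * shade
            trans[idx] *= 1.0 - a_corr
        tcur[active] += step
        if t_global_max and np.all(tcur[active] > t_global_max):
            break

    img = color_acc + trans[:, None] * np.asarray(cfg.background, float)[None, :]
    return np.clip(img.reshape(H, W, 3), 0.0, 1.0)


def branch_pixel_masks(
    field: ScalarField, seg: SegmentationMap, cfg: RenderConfig,
    min_opacity_label: int | None = None,
) -> dict[int, np.ndarray]:
    """Boolean per-branch masks of the pixels whose first-hit deepest branch
    label is that branch (used to measure per-structure image luminance)."""
    dims = field.dims
    spacing = np.array(field.spacing, float)
    pos, forward, right, true_up, extent = _camera_basis(cfg, dims, spacing)
    W, H = cfg.image_size
    oh = cfg.ortho_height if cfg.ortho_height is not None else 1.1 * float(extent.max())
    ow = oh * W / H
    u = (np.arange(W) + 0.5) / W - 0.5
    v = 0.5 - (np.arange(H) + 0.5) / H
    UU, VV = np.meshgrid(u * ow, v * oh)
    origins = (pos[None, None, :] + UU[..., None] * right[None, None, :]
               + VV[..., None] * true_up[None, None, :]).reshape(-1, 3)
    dirs = np.broadcast_to(forward, origins.shape)

    lo = np.zeros(3)
    hi = (np.array(dims, float) - 1.0) * spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = (lo[None, :] - origins) / dirs
        t1 = (hi[None, :] - origins) / dirs
    tmin = np.maximum(np.nanmax(np.minimum(t0, t1), axis=1), 0.0)
    tmax = np.nanmin(np.maximum(t0, t1), axis=1)
    step = cfg.step * float(spacing.min())

    depths_by_label = None
    best = np.full(origins.shape[0], -1, dtype=np.int64)
    best_rank = np.full(origins.shape[0], -1.0)
    t = tmin.copy()
    labels = seg.labels
    while True:
        active = (t <= tmax) & np.isfinite(t)
        if not np.any(active):
            break
        p = origins[active] + t[active, None] * dirs[active]
        coords = (p / spacing[None, :]).T
        inside = np.all((coords >= 0) & (coords <= (np.array(dims)[:, None] - 1)), axis=0)
        if np.any(inside):
            ci = coords[:, inside]
            lab = labels[tuple(np.round(ci).astype(int))]
            idx = np.nonzero(active)[0][inside]
            take = lab > best[idx]  # deeper branch ids are created later
            best[idx[take]] = lab[take]
        t[active] += step
    return {int(b): (best == b).reshape(H, W) for b in np.unique(best) if b >= 0}
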