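"""Synthetic scalar volumes with known, provable topology.

Every generator returns a field whose contour tree is known analytically (up
to the reported approximate saddle values), so the whole pipeline is testable
without downloading data:

* ``ramp_volume`` -- f(x,y,z) = x: a single monotone arc, two leaves.
* ``multi_blob_volume`` -- a sum of isotropic Gaussian bumps with distinct
  heights on a gently tilted background: one maximum leaf per well-separated
  blob, one background minimum; saddle values sit near the inter-blob ridge.
* ``nested_blob_chain`` -- a chain of progressively smaller bumps, each on
  the flank of the previous one, whose merge saddles increase along the
  chain; the branch decomposition is a depth-0..levels-1 chain with nested
  regions (the inclusion structure of concentric/nested anatomy).  Also
  exposed as ``nested_shell_volume``.
* ``add_noise`` -- seeded i.i.d. Gaussian noise, to exercise simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dcfield

import numpy as np

from .field import ScalarField

__all__ = [
    "FixtureSpec",
    "ramp_volume",
    "multi_blob_volume",
    "nested_blob_chain",
    "nested_shell_volume",
    "add_noise",
    "make_fixture",
]

#: slope of the deterministic background tilt that makes all values distinct
#: and pins the background minimum to one corner
_TILT = 1e-4


@dataclass
class FixtureSpec:
    kind: str  # "ramp" | "multi_blob" | "nested_shells"
    dims: tuple[int, int, int] = (24, 24, 24)
    blobs: list[tuple[tuple[float, float, float], float, float]] | None = None
    levels: int = 3
    noise_sigma: float = 0.0
    seed: int = 0


def ramp_volume(dims: tuple[int, int, int],
                spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> ScalarField:
    """f(x,y,z) = x; contour tree is a single arc with persistence nx-1."""
    nx, ny, nz = dims
    x = np.arange(nx, dtype=float)[:, None, None]
    return ScalarField(np.broadcast_to(x, dims).copy(), spacing)


def _grid_coords(dims):
    axes = [np.arange(n, dtype=float) for n in dims]
    return np.meshgrid(*axes, indexing="ij")


def multi_blob_volume(
    dims: tuple[int, int, int],
    blobs: list[tuple[tuple[float, float, float], float, float]],
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ScalarField:
    """Sum of isotropic Gaussian bumps (center in voxel units, height, width).

    Heights must be distinct so the tree is unambiguous; a tiny deterministic
    tilt (~1e-4 per voxel) removes background plateaus.  For well-separated
    blobs the contour tree has one maximum leaf per blob and the child-branch
    persistence equals blob height minus the inter-blob saddle value.
    """
    if not blobs:
        raise ValueError("need at least one blob")
    heights = [h for _, h, _ in blobs]
    if len(set(heights)) != len(heights):
        raise ValueError("blob heights must be distinct")
    centers = [tuple(c) for c, _, _ in blobs]
    if len(set(centers)) != len(centers):
        raise ValueError("blob centers must be distinct")
    X, Y, Z = _grid_coords(dims)
    f = _TILT * (X + 2 * Y + 3 * Z)
    for (cx, cy, cz), h, w in blobs:
        if w <= 0:
            raise ValueError("blob width must be positive")
        r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        f += h * np.exp(-r2 / (2.0 * w**2))
    return ScalarField(f, spacing)


def chain_profile_knots(levels: int) -> tuple[list[float], list[float]]:
    """Designed peak/valley values of the nested chain.

    Peaks decay toward 6 from 10; valleys rise toward 5 from 2.5, so every
    merge saddle v_k lies strictly inside the previous branch's value span
    (v_{k-1}, h_{k-1}) and strictly below its own peak h_k.  Branch k then
    attaches to branch k-1, giving a depth chain.
    """
    peaks = [10.0] + [6.0 + 4.0 * 0.55**k for k in range(1, levels)]
    valleys = [5.0 - 2.5 * 0.5 ** (k - 1) for k in range(1, levels)]
    return peaks, valleys


def _cosine_interp(x: np.ndarray, knots_x: list[float], knots_y: list[float]) -> np.ndarray:
    """Piecewise-cosine interpolation: monotone between knots, smooth at
    them, so no critical values besides the knot values appear."""
    y = np.empty_like(x)
    y[x <= knots_x[0]] = knots_y[0]
    y[x >= knots_x[-1]] = knots_y[-1]
    for (x0, y0), (x1, y1) in zip(zip(knots_x, knots_y), zip(knots_x[1:], knots_y[1:])):
        m = (x >= x0) & (x < x1)
        t = (x[m] - x0) / (x1 - x0)
        y[m] = y0 + (y1 - y0) * (1.0 - np.cos(np.pi * t)) / 2.0
    return y


def nested_blob_chain(
    dims: tuple[int, int, int],
    levels: int,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> ScalarField:
    """Field whose branch decomposition is a depth-0..levels-1 chain.

    An axial profile with designed peaks h_k and valleys v_k (see
    :func:`chain_profile_knots`) is extruded with a radial Gaussian envelope,
    so the only critical points sit on the axis with exactly the designed
    values.  Each bump k merges with the previous one at v_k inside branch
    k-1's value span, so branch k is a child of branch k-1 and the
    superlevel regions nest, emulating contained/nested anatomy.

    Requires about 6 voxels of x-extent per level.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    nx = dims[0]
    need = 9 + 6 * (levels - 1)
    if nx < need:
        raise ValueError(
            f"dims[0]={nx} too small for {levels} levels; need >= {need}")
    peaks, valleys = chain_profile_knots(levels)
    kx = [0.0, 4.0]
    ky = [0.0, peaks[0]]
    for k in range(1, levels):
        kx.extend([kx[-1] + 3.0, kx[-1] + 6.0])
        ky.extend([valleys[k - 1], peaks[k]])
    kx.append(nx - 1.0)
    ky.append(0.0)
    X, Y, Z = _grid_coords(dims)
    cy, cz = (dims[1] - 1) / 2.0, (dims[2] - 1) / 2.0
    sigma = max(min(dims[1], dims[2]) / 5.0, 1.5)
    profile = _cosine_interp(X, kx, ky)
    envelope = np.exp(-((Y - cy) ** 2 + (Z - cz) ** 2) / (2.0 * sigma**2))
    f = profile * envelope + _TILT * (X + 2 * Y + 3 * Z)
    return ScalarField(f, spacing)


def nested_shell_volume(dims, levels, spacing=(1.0, 1.0, 1.0)) -> ScalarField:
    """Alias for :func:`nested_blob_chain` (nested-inclusion fixture)."""
    return nested_blob_chain(dims, levels, spacing)


def add_noise(field: ScalarField, sigma: float, seed: int = 0) -> ScalarField:
    """Add seeded i.i.d. Gaussian noise; sigma = 0 returns an equal field."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return ScalarField(field.values.copy(), field.spacing)
    rng = np.random.default_rng(seed)
    return ScalarField(field.values + rng.normal(0.0, sigma, field.dims),
                       field.spacing)


def make_fixture(spec: FixtureSpec) -> tuple[ScalarField, dict]:
    """Build a fixture and its analytically known tree summary.

    The summary records the expected leaf count and the expected set of
    branch depths after simplification at a threshold below the weakest
    designed feature (test ground truth).
    """
    if spec.kind == "ramp":
        field = ramp_volume(spec.dims)
        summary = {"leaf_count": 2, "depths": {0}, "n_branches": 1}
    elif spec.kind == "multi_blob":
        blobs = spec.blobs
        if blobs is None:
            nx, ny, nz = spec.dims
            blobs = [
                ((nx * 0.28, ny * 0.5, nz * 0.5), 9.0, max(nx * 0.09, 2.0)),
                ((nx * 0.72, ny * 0.5, nz * 0.5), 8.0, max(nx * 0.09, 2.0)),
            ]
        field = multi_blob_volume(spec.dims, blobs)
        summary = {"leaf_count": len(blobs) + 1,
                   "depths": {0} | ({1} if len(blobs) > 1 else set()),
                   "n_branches": len(blobs)}
    elif spec.kind == "nested_shells":
        field = nested_blob_chain(spec.dims, spec.levels)
        summary = {"leaf_count": spec.levels + 1,
                   "depths": set(range(spec.levels)),
                   "n_branches": spec.levels}
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    if spec.noise_sigma > 0:
        field = add_noise(field, spec.noise_sigma, spec.seed)
    return field, summary
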