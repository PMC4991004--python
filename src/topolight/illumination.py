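"""Per-branch lighting coefficients and Blinn-Phong shading.

Three automatic mechanisms map branch topology to illumination:

* attenuation -- a Stokes'-law analogue gives an attenuation coefficient
  alpha = 2*eta*xi^2 / (3*rho*V^3) from a viscosity eta, a density rho, a
  user-controlled speed V and a "frequency" xi taken to be the branch's
  sibling count; Beer-Lambert falloff f_att = exp(-alpha * z) then dims the
  diffuse and specular terms, with the travelled distance z modelled as the
  branch's persistence.
* saliency -- k_d = w * S_i with S_i the topological saliency, so more
  important structures reflect more diffuse light.
* distance -- k_d = w * sigmoid(depth), so deeper (inner) structures are
  brighter.

The water constants default to eta = 0.001002 Pa.s and rho = 998.2071 kg/m^3
(water at 20 C).  With SI constants and speeds in the hundreds the raw
alpha*z product is numerically negligible, so persistence is normalized to
[0, 1] and a documented scale factor is applied; the default scale is
calibrated so that V = 50 with xi = 1 and z = 1 gives f_att = 0.5.  All the
monotonicities of the raw formulas are preserved exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as _dcfield

import numpy as np

from .attributes import BranchAttributes

__all__ = [
    "LightingCoefficients",
    "ShadingSample",
    "AttenuationParams",
    "LtfConfig",
    "LightingTable",
    "shade_blinn_phong",
    "attenuation_coefficient",
    "attenuation_factor",
    "saliency_diffuse",
    "distance_diffuse",
    "build_lighting_table",
    "lighting_table_to_json",
    "lighting_table_from_json",
    "DEFAULT_ATTENUATION_SCALE",
    "WATER_VISCOSITY",
    "WATER_DENSITY",
]

#: dynamic viscosity of water at 20 C [Pa.s]
WATER_VISCOSITY = 0.001002
#: density of water at 20 C [kg/m^3]
WATER_DENSITY = 998.2071

# scale such that alpha * z = ln 2 at V = 50, xi = 1, z = 1 (f_att = 0.5)
DEFAULT_ATTENUATION_SCALE = (
    math.log(2.0) * 3.0 * WATER_DENSITY * 50.0**3 / (2.0 * WATER_VISCOSITY)
)

LTF_MODES = ("attenuation", "saliency", "distance", "perceptual",
             "importance", "constant", "conventional")


@dataclass
class LightingCoefficients:
    """Blinn-Phong coefficients for one branch; all of k_a, k_d, k_s in
    [0, 1], shininess > 0, attenuation factor in (0, 1]."""

    k_a: float = 0.1
    k_d: float = 0.6
    k_s: float = 0.2
    shininess: float = 32.0
    f_att: float = 1.0

    def __post_init__(self) -> None:
        for name in ("k_a", "k_d", "k_s"):
            x = getattr(self, name)
            if not (0.0 <= x <= 1.0):
                raise ValueError(f"{name}={x} outside [0,1]")
        if self.shininess <= 0:
            raise ValueError("shininess must be positive")
        if not (0.0 < self.f_att <= 1.0):
            raise ValueError("f_att must lie in (0,1]")


@dataclass
class ShadingSample:
    """One shaded point: base color from the transfer function, unit normal
    N (zero where the gradient vanishes), unit light direction L and unit
    halfway vector H."""

    base_color: np.ndarray  # RGB in [0,1]^3
    normal: np.ndarray
    light_dir: np.ndarray
    halfway: np.ndarray


@dataclass
class AttenuationParams:
    viscosity: float = WATER_VISCOSITY
    density: float = WATER_DENSITY
    frequency: float = 0.0  # xi: modelled as the branch's sibling count
    speed: float = 50.0  # V: user-controlled
    scale: float = DEFAULT_ATTENUATION_SCALE

    def __post_init__(self) -> None:
        if self.viscosity <= 0 or self.density <= 0:
            raise ValueError("viscosity and density must be positive")
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")
        if self.speed <= 0:
            raise ValueError("speed V must be positive")


@dataclass
class LtfConfig:
    """Lighting-transfer-function configuration.

    ``mode`` picks the topology-to-illumination mechanism; ``weight`` is the
    user weight w; k_a, k_s and the shininess are shared by all branches
    (only the diffuse term varies per structure, plus f_att in attenuation
    mode).
    """

    mode: str = "saliency"
    weight: float = 0.71
    k_a: float = 0.1
    k_s: float = 0.2
    shininess: float = 32.0
    importance_measure: str = "persistence"

    def __post_init__(self) -> None:
        if self.mode not in LTF_MODES:
            raise ValueError(f"unknown mode {self.mode!r}; choose from {LTF_MODES}")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight w must lie in [0,1]")


LightingTable = dict[int, LightingCoefficients]


def shade_blinn_phong(sample: ShadingSample, coeff: LightingCoefficients) -> np.ndarray:
    """Blinn-Phong color with attenuation:

    C = (k_a + k_d * f_att * (N.L)) * C_tf + k_s * f_att * (N.H)^n

    Dot products are clamped to [0, 1] (no negative light); specular color is
    white.  With f_att = 1 this is plain Blinn-Phong.  A zero normal (flat
    gradient) shades with the ambient term only.
    """
    n = np.asarray(sample.normal, dtype=float)
    if float(np.dot(n, n)) < 1e-20:
        return np.clip(coeff.k_a * np.asarray(sample.base_color, float), 0.0, 1.0)
    ndl = float(np.clip(np.dot(n, sample.light_dir), 0.0, 1.0))
    ndh = float(np.clip(np.dot(n, sample.halfway), 0.0, 1.0))
    c = (coeff.k_a + coeff.k_d * coeff.f_att * ndl) * np.asarray(sample.base_color, float)
    c = c + coeff.k_s * coeff.f_att * ndh**coeff.shininess
    return np.clip(c, 0.0, 1.0)


def attenuation_coefficient(ap: AttenuationParams) -> float:
    """alpha = scale * 2*eta*xi^2 / (3*rho*V^3); zero when xi = 0."""
    return ap.scale * 2.0 * ap.viscosity * ap.frequency**2 / (3.0 * ap.density * ap.speed**3)


def attenuation_factor(alpha: float, z: float) -> float:
    """Beer-Lambert falloff f_att = exp(-alpha * z) in (0, 1]."""
    if alpha < 0 or z < 0:
        raise ValueError("alpha and z must be >= 0")
    return float(math.exp(-alpha * z))


def saliency_diffuse(saliency: float, weight: float) -> float:
    """k_d = w * S, clamped to [0, 1]."""
    return float(np.clip(weight * saliency, 0.0, 1.0))


def distance_diffuse(depth: float, weight: float) -> float:
    """k_d = w * sigmoid(depth) = w / (1 + exp(-depth)).

    Strictly increasing in depth with range [w/2, w): deeper (inner)
    structures get more diffuse light.
    """
    if depth < 0:
        raise ValueError("topological depth must be >= 0")
    return float(weight / (1.0 + math.exp(-depth)))


def build_lighting_table(
    attrs: dict[int, BranchAttributes],
    cfg: LtfConfig,
    attenuation: AttenuationParams | None = None,
) -> LightingTable:
    """Assemble per-branch coefficients for the configured mode.

    * ``saliency``: k_d = w * S_i
    * ``distance``: k_d = w * sigmoid(depth_i)
    * ``attenuation``: k_d = w shared; per-branch f_att = exp(-alpha_i * p_i)
      with xi_i = sibling count and p_i persistence normalized over branches
    * ``importance``: k_a = w * normalized measure, k_d = w shared
    * ``constant``: k_d = w for every branch
    * ``conventional``: ambient+diffuse only (k_s = 0), k_d = w

    The ``perceptual`` mode is computed by the perception module
    (two-phase JND model) and rejected here.
    """
    if cfg.mode == "perceptual":
        raise ValueError(
            "perceptual mode is produced by perception.optimize_luminance / "
            "perception.luminance_to_coefficients")
    w = cfg.weight
    table: LightingTable = {}
    pmax = max((a.persistence for a in attrs.values()), default=0.0)
    if cfg.mode == "importance":
        if cfg.importance_measure == "persistence":
            mmax = pmax
            mval = {i: a.persistence for i, a in attrs.items()}
        else:
            mmax = max((a.volume for a in attrs.values()), default=0)
            mval = {i: float(a.volume) for i, a in attrs.items()}
    for i, a in attrs.items():
        k_a, k_s, f_att = cfg.k_a, cfg.k_s, 1.0
        if cfg.mode == "saliency":
            k_d = saliency_diffuse(a.saliency, w)
        elif cfg.mode == "distance":
            k_d = distance_diffuse(a.depth, w)
        elif cfg.mode == "attenuation":
            k_d = w
            ap = attenuation or AttenuationParams()
            alpha = attenuation_coefficient(
                AttenuationParams(viscosity=ap.viscosity, density=ap.density,
                                  frequency=float(a.n_siblings),
                                  speed=ap.speed, scale=ap.scale))
            z = a.persistence / pmax if pmax > 0 else 0.0
            f_att = attenuation_factor(alpha, z)
        elif cfg.mode == "importance":
            k_d = w
            k_a = float(np.clip(w * (mval[i] / mmax if mmax > 0 else 0.0), 0.0, 1.0))
        elif cfg.mode == "constant":
            k_d = w
        else:  # conventional
            k_d = w
            k_s = 0.0
        table[i] = LightingCoefficients(k_a=k_a, k_d=k_d, k_s=k_s,
                                        shininess=cfg.shininess, f_att=f_att)
    return table


def lighting_table_to_json(table: LightingTable) -> str:
    return json.dumps({
        str(i): {"ka": c.k_a, "kd": c.k_d, "ks": c.k_s,
                 "n": c.shininess, "f_att": c.f_att}
        for i, c in sorted(table.items())
    }, indent=2)


def lighting_table_from_json(text: str) -> LightingTable:
    raw = json.loads(text)
    return {
        int(i): LightingCoefficients(k_a=d["ka"], k_d=d["kd"], k_s=d["ks"],
                                     shininess=d["n"], f_att=d["f_att"])
        for i, d in raw.items()
    }
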