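"""Volume readers/writers, artifact serialization, and the pipeline runner.

Volumes are exchanged in two dialects:

* raw binary plus a sidecar text header (``.raw`` + ``.hdr``) with keys
  ``dims``, ``dtype``, ``spacing``, ``byteorder``;
* NRRD with raw encoding (a small self-contained codec: NRRD files are a
  text header followed by the raw payload).

Voxel order is x-fastest (0-based indices, Fortran raveling), matching the
rest of the package.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as _dcfield, asdict
from pathlib import Path

import numpy as np

from .attributes import SaliencyParams, annotate_structure, attributes_to_frame
from .contour_tree import (BranchDecomposition, SegmentationMap,
                           build_contour_tree, decompose_branches,
                           segment_field, simplify_tree)
from .field import ScalarField
from .illumination import (AttenuationParams, LtfConfig, build_lighting_table,
                           lighting_table_to_json)
from .perception import (ContrastFlowParams, luminance_to_coefficients,
                         optimize_luminance)
from .renderer import (RenderConfig, TransferFunction,
                       default_transfer_function, raycast_image)

logger = logging.getLogger("topolight")

__all__ = [
    "VolumeHeader",
    "PipelineConfig",
    "read_volume",
    "write_volume",
    "read_raw",
    "write_raw",
    "read_nrrd",
    "write_nrrd",
    "write_ppm",
    "write_png",
    "run_pipeline",
]

_DTYPES = {"uint8": np.uint8, "uint16": np.uint16, "float32": np.float32}


@dataclass
class VolumeHeader:
    dims: tuple[int, int, int]
    dtype: str = "float32"
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    byteorder: str = "little"

    def __post_init__(self) -> None:
        if self.dtype not in _DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r}; supported: {sorted(_DTYPES)}")
        if self.byteorder not in ("little", "big"):
            raise ValueError("byteorder must be 'little' or 'big'")

    @property
    def numpy_dtype(self) -> np.dtype:
        dt = np.dtype(_DTYPES[self.dtype])
        return dt.newbyteorder("<" if self.byteorder == "little" else ">")

    @property
    def payload_bytes(self) -> int:
        return int(np.prod(self.dims)) * self.numpy_dtype.itemsize


def _header_path(raw_path: Path) -> Path:
    return raw_path.with_suffix(".hdr")


def write_raw(field: ScalarField, path: str | Path, dtype: str = "float32") -> Path:
    """Write raw payload + sidecar .hdr; returns the raw path."""
    path = Path(path)
    hdr = VolumeHeader(dims=field.dims, dtype=dtype, spacing=field.spacing)
    data = field.values
    if dtype != "float32":
        info = np.iinfo(_DTYPES[dtype])
        lo, hi = field.value_range
        scale = (info.max if hi > lo else 0) / (hi - lo if hi > lo else 1.0)
        data = np.round((data - lo) * scale)
    data.astype(hdr.numpy_dtype).ravel(order="F").tofile(path)
    lines = [
        f"dims: {hdr.dims[0]} {hdr.dims[1]} {hdr.dims[2]}",
        f"dtype: {hdr.dtype}",
        f"spacing: {hdr.spacing[0]} {hdr.spacing[1]} {hdr.spacing[2]}",
        f"byteorder: {hdr.byteorder}",
    ]
    _header_path(path).write_text("\n".join(lines) + "\n")
    return path


def read_raw(path: str | Path, header: VolumeHeader | None = None) -> ScalarField:
    path = Path(path)
    if header is None:
        hp = _header_path(path)
        if not hp.exists():
            raise FileNotFoundError(f"no sidecar header {hp} for {path}")
        kv = {}
        for line in hp.read_text().splitlines():
            if ":" in line:
                k, v = line.split(":", 1)
                kv[k.strip()] = v.strip()
        header = VolumeHeader(
            dims=tuple(int(x) for x in kv["dims"].split()),
            dtype=kv.get("dtype", "float32"),
            spacing=tuple(float(x) for x in kv.get("spacing", "1 1 1").split()),
            byteorder=kv.get("byteorder", "little"),
        )
    blob = Path(path).read_bytes()
    if len(blob) != header.payload_bytes:
        raise ValueError(
            f"size mismatch: file has {len(blob)} bytes, header implies "
            f"{header.payload_bytes} ({header.dims} x {header.dtype})")
    arr = np.frombuffer(blob, dtype=header.numpy_dtype)
    values = arr.astype(np.float64).reshape(header.dims, order="F")
    return ScalarField(values, header.spacing)


def write_nrrd(field: ScalarField, path: str | Path, dtype: str = "float32") -> Path:
    """Minimal NRRD writer (raw encoding, attached header)."""
    path = Path(path)
    hdr = VolumeHeader(dims=field.dims, dtype=dtype, spacing=field.spacing)
    data = field.values
    if dtype != "float32":
        info = np.iinfo(_DTYPES[dtype])
        lo, hi = field.value_range
        scale = (info.max if hi > lo else 0) / (hi - lo if hi > lo else 1.0)
        data = np.round((data - lo) * scale)
    type_names = {"uint8": "uint8", "uint16": "uint16", "float32": "float"}
    lines = [
        "NRRD0004",
        "# produced by topolight",
        f"type: {type_names[dtype]}",
        "dimension: 3",
        f"sizes: {field.dims[0]} {field.dims[1]} {field.dims[2]}",
        f"spacings: {field.spacing[0]} {field.spacing[1]} {field.spacing[2]}",
        "endian: little",
        "encoding: raw",
    ]
    payload = data.astype(hdr.numpy_dtype).ravel(order="F").tobytes()
    path.write_bytes(("\n".join(lines) + "\n\n").encode() + payload)
    return path


def read_nrrd(path: str | Path) -> ScalarField:
    """Minimal NRRD reader: raw encoding, attached header, 3D."""
    blob = Path(path).read_bytes()
    sep = blob.find(b"\n\n")
    if not blob.startswith(b"NRRD") or sep < 0:
        raise ValueError(f"{path} is not an attached-header NRRD file")
    fields: dict[str, str] = {}
    for line in blob[:sep].decode("ascii", "replace").splitlines()[1:]:
        if line.startswith("#") or ":" not in line:
            continue
        k, v = line.split(":", 1)
        fields[k.strip().lower()] = v.strip()
    if fields.get("encoding", "raw") != "raw":
        raise ValueError(f"unsupported NRRD encoding {fields.get('encoding')!r}")
    typemap = {"uint8": "uint8", "uchar": "uint8", "uint16": "uint16",
               "ushort": "uint16", "float": "float32", "float32": "float32"}
    t = fields.get("type", "float")
    if t not in typemap:
        raise ValueError(f"unsupported NRRD type {t!r}")
    dims = tuple(int(x) for x in fields["sizes"].split())
    if len(dims) != 3:
        raise ValueError("only 3D NRRD volumes are supported")
    spacing = tuple(float(x) for x in fields.get("spacings", "1 1 1").split())
    header = VolumeHeader(dims=dims, dtype=typemap[t], spacing=spacing,
                          byteorder=fields.get("endian", "little"))
    payload = blob[sep + 2:]
    if len(payload) != header.payload_bytes:
        raise ValueError(
            f"size mismatch: payload has {len(payload)} bytes, header implies "
            f"{header.payload_bytes}")
    arr = np.frombuffer(payload, dtype=header.numpy_dtype)
    return ScalarField(arr.astype(np.float64).reshape(dims, order="F"), spacing)


def read_volume(path: str | Path, header: VolumeHeader | None = None) -> ScalarField:
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        return read_nrrd(path)
    return read_raw(path, header)


def write_volume(field: ScalarField, path: str | Path, dtype: str = "float32") -> Path:
    path = Path(path)
    if path.suffix.lower() == ".nrrd":
        return write_nrrd(field, path, dtype)
    return write_raw(field, path, dtype)


def write_segmentation(seg: SegmentationMap, path: str | Path) -> Path:
    """Segmentation labels as a uint16 volume (raw or NRRD by extension)."""
    f = ScalarField(seg.labels.astype(np.float64))
    return write_volume(f, path, dtype="uint16")


def write_ppm(image: np.ndarray, path: str | Path) -> Path:
    """Plain-text PPM (P3) — dependency-free golden-image format."""
    path = Path(path)
    h, w, _ = image.shape
    data = np.clip(np.round(image * 255), 0, 255).astype(int)
    rows = [" ".join(str(x) for x in row.ravel()) for row in data]
    path.write_text(f"P3\n{w} {h}\n255\n" + "\n".join(rows) + "\n")
    return path


def write_png(image: np.ndarray, path: str | Path) -> Path:
    from PIL import Image

    arr = np.clip(np.round(image * 255), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))
    return Path(path)


@dataclass
class PipelineConfig:
    """All user-controlled quantities of the pipeline in one place."""

    connectivity: int = 6
    simplify_measure: str = "persistence"
    simplify_threshold: float = 0.0
    mode: str = "saliency"
    weight: float = 0.71
    speed: float = 50.0  # attenuation speed V
    Q: float = 1.0
    K: float = 300.0
    L0: float = 10.0
    gamma0: float = 0.8
    k_a: float = 0.1
    k_s: float = 0.2
    shininess: float = 32.0
    attenuation_scale: float | None = None
    image_size: tuple[int, int] = (64, 64)
    seed: int = 0


def run_pipeline(
    cfg: PipelineConfig,
    field: ScalarField,
    out_prefix: str | Path | None = None,
    tf: TransferFunction | None = None,
) -> dict:
    """build -> simplify -> segment -> annotate -> illuminate -> render.

    Returns the in-memory artifacts; when ``out_prefix`` is given also writes
    tree JSON, attribute CSV, lighting JSON, PPM/PNG images and the config.
    """
    stage = "build-tree"
    try:
        ct = build_contour_tree(field, cfg.connectivity)
        bd = decompose_branches(ct, cfg.simplify_measure)
        stage = "simplify"
        if cfg.simplify_threshold > 0:
            bd = simplify_tree(bd, cfg.simplify_measure,
                               threshold=cfg.simplify_threshold)
        stage = "segment"
        seg = segment_field(field, bd)
        stage = "annotate"
        attrs = annotate_structure(bd, field, seg)
        stage = "illuminate"
        if cfg.mode == "perceptual":
            la = optimize_luminance(
                bd, attrs,
                ContrastFlowParams(L0=cfg.L0, gamma0=cfg.gamma0, Q=cfg.Q, K=cfg.K))
            ltf = LtfConfig(mode="saliency", weight=cfg.weight, k_a=cfg.k_a,
                            k_s=cfg.k_s, shininess=cfg.shininess)
            table = luminance_to_coefficients(la, ltf)
            luminance = la
        else:
            ap_kwargs = {"speed": cfg.speed}
            if cfg.attenuation_scale is not None:
                ap_kwargs["scale"] = cfg.attenuation_scale
            table = build_lighting_table(
                attrs,
                LtfConfig(mode=cfg.mode, weight=cfg.weight, k_a=cfg.k_a,
                          k_s=cfg.k_s, shininess=cfg.shininess),
                AttenuationParams(**ap_kwargs))
            luminance = None
        stage = "render"
        tf = tf or default_transfer_function(bd)
        rc = RenderConfig(image_size=cfg.image_size)
        image = raycast_image(field, seg, table, tf, rc)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts = {"tree": bd, "segmentation": seg, "attributes": attrs,
                 "lighting": table, "image": image, "luminance": luminance,
                 "transfer_function": tf}
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}_tree.json").write_text(json.dumps(bd.to_dict(), indent=2))
        attributes_to_frame(attrs).to_csv(f"{prefix}_attrs.csv", index=False)
        Path(f"{prefix}_lighting.json").write_text(lighting_table_to_json(table))
        Path(f"{prefix}_tf.json").write_text(json.dumps(tf.to_dict(), indent=2))
        write_ppm(image, f"{prefix}_image.ppm")
        write_png(image, f"{prefix}_image.png")
        cfgd = asdict(cfg)
        cfgd["image_size"] = list(cfg.image_size)
        Path(f"{prefix}_config.json").write_text(json.dumps(cfgd, indent=2))
        if luminance is not None:
            luminance.diagnostics_frame().to_csv(
                f"{prefix}_perception.csv", index=False)
        logger.info("pipeline artifacts written with prefix %s", prefix)
    return artifacts
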