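"""Readers and writers for the pipeline's on-disk formats.

* Polarization stacks: multi-page TIFF, one page per illumination angle,
  with a sidecar JSON (``angles_deg``, ``pixel_size_um``, ``bit_depth``).
* Parameter maps: 2-page 32-bit TIFF (relative retardance, orientation).
* RGB renderings: 8- or 16-bit PNG/TIFF.
* Annotations and detections: COCO-format JSON with the single category
  ``myelin_defect``; detections additionally carry a ``score``.
* ROIs: JSON polygon; densities: CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import ParameterMap, PolarizationStack
from .detect import BoundingBox, Detection
from .quantify import ROI

__all__ = [
    "write_stack",
    "read_stack",
    "write_parameter_map",
    "read_parameter_map",
    "write_rgb",
    "read_rgb",
    "write_boxes",
    "read_boxes",
    "write_roi",
    "read_roi",
]

CATEGORY_NAME = "myelin_defect"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(path: str | Path, stack: PolarizationStack) -> Path:
    """Write a polarization stack as multi-page TIFF + sidecar JSON."""
    path = Path(path)
    frames = stack.frames
    if frames.dtype.kind == "f":
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta = {
        "angles_deg": [float(a) for a in stack.angles_deg],
        "pixel_size_um": float(stack.pixel_size_um),
        "bit_depth": int(frames.dtype.itemsize * 8),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(
    path: str | Path, i0: float = 1.0, sidecar: str | Path | None = None
) -> PolarizationStack:
    """Read a stack written by :func:`write_stack`; validates >= 3 angles.

    The angle metadata comes from the sidecar JSON next to the TIFF
    (``<name>.tif.json``) unless an explicit ``sidecar`` path is given.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar JSON for stack: {sidecar}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    return PolarizationStack(
        frames=np.asarray(frames),
        angles_deg=np.asarray(meta["angles_deg"], dtype=float),
        i0=i0,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


def write_parameter_map(path: str | Path, pmap: ParameterMap) -> Path:
    """Store (retardance, orientation) as a 2-page 32-bit TIFF."""
    path = Path(path)
    pages = np.stack(
        [
            pmap.retardance_rel.astype(np.float32),
            pmap.orientation_deg.astype(np.float32),
        ]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {"pixel_size_um": float(pmap.pixel_size_um), "pages": ["retardance_rel", "orientation_deg"]}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_parameter_map(
    path: str | Path, retardance_floor: float = 0.01
) -> ParameterMap:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.shape[0] != 2:
        raise ValueError("parameter map TIFF must have exactly 2 pages")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    ret = np.asarray(pages[0], dtype=float)
    return ParameterMap(
        retardance_rel=ret,
        orientation_deg=np.asarray(pages[1], dtype=float),
        validity_mask=ret >= retardance_floor,
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
    )


def write_rgb(path: str | Path, rgb: np.ndarray, bits: int = 8) -> Path:
    """Write a float RGB image in [0, 1] as 8-bit PNG/TIFF or 16-bit TIFF.

    16-bit RGB is TIFF-only (PNG writers here cap RGB at 8 bits).
    """
    path = Path(path)
    is_tiff = path.suffix.lower() in (".tif", ".tiff")
    if bits == 8:
        data = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    elif bits == 16:
        if not is_tiff:
            raise ValueError("16-bit RGB output requires a .tif/.tiff path")
        data = np.round(np.clip(rgb, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    if is_tiff:
        tifffile.imwrite(path, data, photometric="rgb")
    else:
        iio.imwrite(path, data)
    return path


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an RGB image back to float in [0, 1] (channel order preserved)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    data = np.asarray(data)
    if data.ndim != 3 or data.shape[-1] < 3:
        raise ValueError(f"not an RGB image: {path}")
    data = data[..., :3]
    scale = 255.0 if data.dtype == np.uint8 else 65535.0
    return data.astype(float) / scale


# ---------------------------------------------------------------------------
# COCO-format boxes


def write_boxes(
    path: str | Path,
    detections: list[Detection] | list[BoundingBox],
    image_size: tuple[int, int] | None = None,
    image_name: str = "image",
) -> Path:
    """Write boxes/detections as COCO JSON (single ``myelin_defect`` class)."""
    path = Path(path)
    annotations = []
    for k, det in enumerate(detections):
        box = det.box if isinstance(det, Detection) else det
        record = {
            "id": k + 1,
            "image_id": 1,
            "category_id": 1,
            "bbox": [box.x, box.y, box.width, box.height],
            "area": box.area,
            "iscrowd": 0,
        }
        if isinstance(det, Detection):
            record["score"] = det.confidence
        annotations.append(record)
    image_entry = {"id": 1, "file_name": image_name}
    if image_size is not None:
        image_entry["height"], image_entry["width"] = image_size
    doc = {
        "images": [image_entry],
        "annotations": annotations,
        "categories": [{"id": 1, "name": CATEGORY_NAME}],
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_boxes(path: str | Path) -> list[Detection]:
    """Read COCO JSON back into detections (score defaults to 1.0).

    Rejects malformed records (non-positive box dimensions) identifying
    the offending annotation id.
    """
    doc = json.loads(Path(path).read_text())
    cats = {c["id"]: c["name"] for c in doc.get("categories", [])}
    out = []
    for rec in doc.get("annotations", []):
        name = cats.get(rec.get("category_id"))
        if name is not None and name != CATEGORY_NAME:
            raise ValueError(f"unexpected category {name!r} in annotation {rec.get('id')}")
        x, y, w, h = rec["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(
                f"annotation id={rec.get('id')} has non-positive box dimensions {rec['bbox']}"
            )
        out.append(
            Detection(BoundingBox(x, y, w, h), float(rec.get("score", 1.0)))
        )
    return out


# ---------------------------------------------------------------------------
# ROI JSON


def write_roi(path: str | Path, roi: ROI) -> Path:
    if roi.polygon is None:
        raise ValueError("only polygon ROIs are serialized as JSON")
    doc = {
        "pixel_size_um": roi.pixel_size_um,
        "polygon": [[float(x), float(y)] for x, y in roi.polygon],
    }
    Path(path).write_text(json.dumps(doc, indent=1))
    return Path(path)


def read_roi(path: str | Path) -> ROI:
    doc = json.loads(Path(path).read_text())
    return ROI(
        polygon=[(float(x), float(y)) for x, y in doc["polygon"]],
        pixel_size_um=float(doc["pixel_size_um"]),
    )
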