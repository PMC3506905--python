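"""Readers and writers for the standard on-disk formats.

Volumes are NIfTI-1 with the voxel size in the header and a diagonal affine
(world = index * voxel_size, 0-based indices, axis order (x, y, z)); slides
are 8-bit RGB PNG/TIFF; content maps are 32-bit float TIFF; specs and
pipeline configs are YAML; tables are CSV; transforms and reports are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
import yaml
from PIL import Image

from . import phantom as ph

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_slide",
    "load_slide",
    "save_content_map",
    "load_content_map",
    "spec_to_dict",
    "spec_from_dict",
    "save_spec",
    "load_spec",
    "write_manifest",
]


def save_nifti(data: np.ndarray, voxel_size: float, path) -> Path:
    """Write a volume as NIfTI-1. World coordinates: index * voxel_size (mm),
    0-based (x, y, z) indices, diagonal affine."""
    path = Path(path)
    affine = np.diag([voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms((voxel_size,) * 3)
    nib.save(img, str(path))
    return path


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    voxel_size = float(img.header.get_zooms()[0])
    return data, voxel_size


def save_slide(slide: ph.SlideImage, path) -> Path:
    """Write an RGB slide as PNG or TIFF (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), slide.data)
    else:
        Image.fromarray(slide.data).save(str(path))
    return path


def load_slide(path, pixel_size_um: float) -> ph.SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(str(path))
    else:
        data = np.asarray(Image.open(str(path)).convert("RGB"))
    return ph.SlideImage(np.asarray(data, dtype=np.uint8), pixel_size_um)


def save_content_map(content, path) -> Path:
    """Write a myelin content map as 32-bit float TIFF (% area)."""
    path = Path(path)
    tifffile.imwrite(str(path), np.asarray(content.data, dtype=np.float32))
    return path


def load_content_map(path, pixel_size_mm: float):
    from .histology import MyelinContentMap

    data = tifffile.imread(str(path)).astype(np.float64)
    return MyelinContentMap(data, pixel_size_mm)


# ---------------------------------------------------------------------------
# spec (de)serialization
# ---------------------------------------------------------------------------

def spec_to_dict(spec: ph.PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["tissue_table"] = {k: dataclasses.asdict(v) for k, v in spec.tissue_table.items()}
    if spec.lesion_specs is not None:
        d["lesion_specs"] = [dataclasses.asdict(l) for l in spec.lesion_specs]
    if spec.banding_defect is not None:
        d["banding_defect"] = dataclasses.asdict(spec.banding_defect)
    for key in ("grid_shape", "fold_order"):
        d[key] = list(d[key])
    return d


def spec_from_dict(d: dict) -> ph.PhantomSpec:
    d = dict(d)
    d["grid_shape"] = tuple(d.get("grid_shape", (128, 128, 128)))
    if "fold_order" in d:
        d["fold_order"] = tuple(d["fold_order"])
    if d.get("tissue_table"):
        d["tissue_table"] = {
            k: ph.TissueRow(**v) for k, v in d["tissue_table"].items()
        }
    if d.get("lesion_specs"):
        d["lesion_specs"] = [
            ph.LesionSpec(**{**l, "center": tuple(l["center"])})
            for l in d["lesion_specs"]
        ]
    if d.get("banding_defect"):
        bd = dict(d["banding_defect"])
        bd["center"] = tuple(bd["center"])
        bd["factors"] = tuple(bd.get("factors", (0.6, 0.4)))
        d["banding_defect"] = ph.BandingDefectSpec(**bd)
    return ph.PhantomSpec(**d)


def save_spec(spec: ph.PhantomSpec, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_dict(spec), fh, sort_keys=True)
    return path


def load_spec(path) -> ph.PhantomSpec:
    with open(path) as fh:
        return spec_from_dict(yaml.safe_load(fh))


def write_manifest(entries: dict, path) -> Path:
    """Deterministic JSON manifest (sorted keys, no timestamps)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
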