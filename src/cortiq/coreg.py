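"""Histology-to-MR coregistration via tag-point affine transforms.

Slide-space regions of interest are mapped into the MR slab frame with a
least-squares 2D affine fitted to manually picked tag-point pairs, and
coronal planes of any volumetric map are extracted for voxel-matched
comparison. Units are mm throughout; pixel/voxel centers sit at
index * pixel_size (0-based indices, axis order (x, y) in-plane and
(x, y, z) in volumes; coronal planes are constant-y).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "AffineTransform2D",
    "fit_affine_tags",
    "load_tag_points",
    "apply_affine",
    "extract_slab_plane",
]


@dataclass(frozen=True)
class AffineTransform2D:
    """y = A x + t with an invertible 2x2 linear part; mm units."""

    linear: tuple[tuple[float, float], tuple[float, float]]
    translation: tuple[float, float]

    def __post_init__(self):
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part must be invertible")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.linear, dtype=np.float64)

    @property
    def offset(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=np.float64)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(((1.0, 0.0), (0.0, 1.0)), (0.0, 0.0))

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=np.float64)
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        t = -inv @ self.offset
        return AffineTransform2D(tuple(map(tuple, inv)), tuple(t))

    def to_json(self) -> str:
        """Row-major 2x3 matrix [A | t] in mm."""
        m = np.hstack([self.matrix, self.offset[:, None]])
        return json.dumps({"affine_2x3_mm": m.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "AffineTransform2D":
        m = np.asarray(json.loads(text)["affine_2x3_mm"], dtype=np.float64)
        return cls(tuple(map(tuple, m[:, :2])), tuple(m[:, 2]))


def fit_affine_tags(
    src: np.ndarray, dst: np.ndarray
) -> tuple[AffineTransform2D, float]:
    """Least-squares affine from >= 3 tag-point pairs (slide mm -> MR mm).

    Minimizes the sum of squared target residuals; returns the transform and
    the RMS residual in mm. Degenerate configurations (fewer than 3 pairs, or
    all source points collinear) raise.
    """
    src = np.asarray(src, dtype=np.float64)
    dst = np.asarray(dst, dtype=np.float64)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("tag points must be two matched (n, 2) arrays")
    n = src.shape[0]
    if n < 3:
        raise ValueError("at least 3 tag-point pairs are required")
    design = np.hstack([src, np.ones((n, 1))])
    if np.linalg.matrix_rank(design, tol=1e-9 * max(1.0, np.abs(src).max())) < 3:
        raise ValueError("degenerate tag points: source points are collinear")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    linear = coef[:2, :].T
    t = coef[2, :]
    fitted = design @ coef
    rms = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    return AffineTransform2D(tuple(map(tuple, linear)), tuple(t)), rms


def load_tag_points(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a tag-point CSV with columns x_src, y_src, x_dst, y_dst (mm)."""
    tab = pd.read_csv(path)
    src = tab[["x_src", "y_src"]].to_numpy(dtype=np.float64)
    dst = tab[["x_dst", "y_dst"]].to_numpy(dtype=np.float64)
    return src, dst


def apply_affine(
    image: np.ndarray,
    transform: AffineTransform2D,
    output_shape: tuple[int, int],
    pixel_size: float,
    src_pixel_size: float | None = None,
    is_label: bool = False,
    background=0,
):
    """Resample a 2D image through the affine onto a target grid.

    The transform maps source mm coordinates to target mm coordinates; each
    target pixel center is pulled back through the inverse. Label images use
    nearest-neighbour interpolation (classes are never blended), continuous
    maps are linearly interpolated; pull-backs landing outside the source
    grid receive ``background``.
    """
    image = np.asarray(image)
    if src_pixel_size is None:
        src_pixel_size = pixel_size
    inv = transform.inverse()
    ii, jj = np.meshgrid(
        np.arange(output_shape[0]), np.arange(output_shape[1]), indexing="ij"
    )
    tgt_mm = np.stack([ii.ravel() * pixel_size, jj.ravel() * pixel_size], axis=1)
    src_mm = inv.apply_points(tgt_mm)
    coords = (src_mm / src_pixel_size).T.reshape(2, *output_shape)
    order = 0 if is_label else 1
    out = ndimage.map_coordinates(
        image.astype(np.float64), coords, order=order, mode="constant",
        cval=float(background),
    )
    if is_label:
        out = out.astype(image.dtype)
    return out


def extract_slab_plane(
    volume: np.ndarray, plane_index: int, voxel_size: float, axis: int = 1
) -> tuple[np.ndarray, dict]:
    """Extract one coronal (constant-y by default) plane of a volume.

    Returns the 2D plane and world metadata: the fixed-axis coordinate and
    the mm coordinates of the plane corners (index * voxel_size convention).
    Out-of-range indices raise.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("extract_slab_plane expects a 3D volume")
    if not 0 <= plane_index < volume.shape[axis]:
        raise IndexError(
            f"plane index {plane_index} out of range for axis {axis} "
            f"(size {volume.shape[axis]})"
        )
    plane = np.take(volume, plane_index, axis=axis)
    in_plane_axes = [a for a in range(3) if a != axis]
    extent = [(volume.shape[a] - 1) * voxel_size for a in in_plane_axes]
    meta = {
        "axis": axis,
        "plane_index": plane_index,
        "plane_world_mm": plane_index * voxel_size,
        "corner_00_mm": (0.0, 0.0),
        "corner_11_mm": tuple(extent),
        "voxel_size_mm": voxel_size,
    }
    return plane, meta
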