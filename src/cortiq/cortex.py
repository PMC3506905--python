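"""Cortical mask hygiene and laminar depth analysis.

The cortical ribbon is analysed voxel-wise: a 6-connectivity erosion strips
the single partial-volume layer at the pial and WM boundaries, and a
distance-transform depth field assigns every cortical voxel its fractional
laminar position between the pial surface (0) and the WM boundary (1).
Quantitative maps can then be sampled in narrow bands at fixed depths to
build laminar profiles.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom import CORTICAL, WM_LIKE, LabelVolume, Tissue

__all__ = ["erode_mask_6conn", "depth_field", "sample_at_depth"]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def erode_mask_6conn(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Erode a 3D binary mask with the 6-connectivity (face-neighbour) kernel.

    A voxel survives one pass iff it and all six face neighbours are inside
    the mask; voxels on the array border are treated as having outside
    neighbours. One pass removes exactly the face-boundary layer; the result
    is always a subset of the input.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("erode_mask_6conn expects a 3D mask")
    if iterations < 1:
        return mask.copy()
    return ndimage.binary_erosion(
        mask, structure=_STRUCT6, iterations=iterations, border_value=0
    )


def depth_field(labels: LabelVolume) -> np.ndarray:
    """Fractional cortical depth from the pial surface, per cortical voxel.

    For every voxel of the cortical ribbon (cortex plus cortical lesions —
    lesions remain part of the ribbon for depth purposes),

        d = Dp / (Dp + Dw)

    where Dp is the Euclidean distance (mm) to the nearest non-brain
    (formalin) voxel and Dw the distance to the nearest WM-like voxel
    (white matter, WM lesion, or subcortical grey relabeled as WM).
    d = 0 at the pial boundary, d -> 1 at the WM boundary; NaN outside the
    ribbon.

    Raises if a connected cortical component lacks either boundary (no
    face-adjacent formalin or WM-like voxel), naming the component.
    """
    lab = labels.data
    cortical = np.isin(lab, [int(t) for t in CORTICAL])
    nonbrain = lab == int(Tissue.FORMALIN)
    wmlike = np.isin(lab, [int(t) for t in WM_LIKE])

    if cortical.any():
        comp, ncomp = ndimage.label(cortical, structure=np.ones((3, 3, 3), bool))
        grown_nb = ndimage.binary_dilation(nonbrain, structure=_STRUCT6)
        grown_wm = ndimage.binary_dilation(wmlike, structure=_STRUCT6)
        for c in range(1, ncomp + 1):
            sel = comp == c
            if not (sel & grown_nb).any():
                raise ValueError(f"cortical component {c} has no pial (formalin) boundary")
            if not (sel & grown_wm).any():
                raise ValueError(f"cortical component {c} has no WM boundary")

    vox = labels.voxel_size
    # distance_transform_edt measures distance to the nearest zero voxel
    dp = ndimage.distance_transform_edt(~nonbrain, sampling=vox)
    dw = ndimage.distance_transform_edt(~wmlike, sampling=vox)

    depth = np.full(lab.shape, np.nan, dtype=np.float64)
    denom = dp + dw
    with np.errstate(invalid="ignore"):
        depth[cortical] = dp[cortical] / denom[cortical]
    return depth


def sample_at_depth(
    qmap: np.ndarray,
    depth: np.ndarray,
    fraction: float,
    band: float = 0.05,
    valid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Values of ``qmap`` in the depth band ``|d - fraction| <= band``.

    Returns a table with columns x, y, z, depth, value (0-based voxel
    indices). An empty band yields an empty table, not an error. ``valid``
    optionally restricts sampling (e.g. to fit-valid, non-excluded voxels).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("depth fraction must lie in (0, 1)")
    sel = np.isfinite(depth) & (np.abs(depth - fraction) <= band)
    if valid is not None:
        sel &= valid
    coords = np.argwhere(sel)
    return pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "depth": depth[sel],
            "value": np.asarray(qmap)[sel],
        }
    )


def depth_summary(
    qmap: np.ndarray,
    depth: np.ndarray,
    fractions=(0.25, 0.5, 0.75),
    band: float = 0.05,
    valid: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Mean/SD/n of ``qmap`` per depth band — the laminar profile table."""
    rows = []
    for f in fractions:
        tab = sample_at_depth(qmap, depth, f, band, valid)
        vals = tab["value"].to_numpy()
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "depth_fraction": f,
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)
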