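"""Inversion of the acquisitions into quantitative maps.

Closed-form two-point fits, matching the two-angle protocol the package
emulates:

* double-angle B1 mapping — per-voxel solution of the quadratic
  2 c^2 - r c - 1 = 0 linking the signal ratio r = S2/S1 to c = cos(theta),
* variable-flip-angle T1/M0 from two SPGR volumes (linearized fit),
* T2 from two balanced SSFP volumes given T1 (linearized fit),
* MTR as the percent signal drop of the saturated SPGR volume,
* a banding exclusion mask for off-resonance-corrupted bSSFP regions.

Every fit carries an explicit validity mask; voxels where the closed form
has no physical solution are flagged, never clamped or silently filled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .phantom import B1Map, SignalVolume

__all__ = [
    "QMaps",
    "compute_b1",
    "upsample_b1",
    "fit_despot1",
    "fit_despot2",
    "compute_mtr",
    "banding_exclusion_mask",
    "fit_qmaps",
]


@dataclass
class QMaps:
    """Fitted quantitative maps with per-map validity masks.

    A voxel is usable for a given parameter iff the corresponding validity
    mask is True there; ``excluded`` carries the banding exclusion, applied
    on top of validity by downstream statistics.
    """

    t1: np.ndarray
    t2: np.ndarray
    m0: np.ndarray
    mtr: np.ndarray
    valid: dict[str, np.ndarray] = field(default_factory=dict)
    excluded: Optional[np.ndarray] = None

    def usable(self, param: str) -> np.ndarray:
        ok = self.valid[param].copy()
        if self.excluded is not None and param in ("t2",):
            ok &= ~self.excluded
        return ok


def compute_b1(
    s1: SignalVolume, s2: SignalVolume, nominal_deg: float = 20.0
) -> B1Map:
    """Transmit-field map from a double-angle (alpha, 2*alpha) pair.

    With S1 ∝ cos(theta), S2 ∝ cos(2*theta) and r = S2/S1, the identity
    cos(2t) = 2 cos^2(t) - 1 gives the quadratic 2 c^2 - r c - 1 = 0 in
    c = cos(theta); the root in (0, 1) is c = (r + sqrt(r^2 + 8)) / 4, and
    b1 = theta / nominal. Voxels with r >= 1 (no theta in (0, 90) deg), a
    non-positive S1, or non-finite inputs are flagged invalid.
    """
    a = np.asarray(s1.data, dtype=np.float64)
    b = np.asarray(s2.data, dtype=np.float64)
    valid = np.isfinite(a) & np.isfinite(b) & (a > 0)
    r = np.full(a.shape, np.nan)
    np.divide(b, a, out=r, where=valid)
    c = (r + np.sqrt(r * r + 8.0)) / 4.0
    valid &= np.isfinite(c) & (c > 0.0) & (c < 1.0)  # c = 1 <=> theta = 0, degenerate
    theta = np.full(a.shape, np.nan)
    np.arccos(c, out=theta, where=valid)
    b1 = np.full(a.shape, np.nan)
    b1[valid] = np.degrees(theta[valid]) / nominal_deg
    return B1Map(b1, s1.voxel_size, valid=valid)


def upsample_b1(b1: B1Map, target_shape: tuple[int, int, int]) -> B1Map:
    """Trilinear upsampling of a coarse-grid B1 map onto the signal grid.

    The transmit field is smooth by construction, so a coarse native grid
    followed by trilinear interpolation loses little; invalid coarse voxels
    are filled with 1.0 before interpolation and their neighbourhood is
    flagged invalid on the fine grid.
    """
    data = b1.data.copy()
    invalid = ~b1.valid if b1.valid is not None else ~np.isfinite(data)
    data[invalid] = 1.0
    zoom = [t / s for t, s in zip(target_shape, data.shape)]
    fine = ndimage.zoom(data, zoom, order=1, mode="nearest", grid_mode=True)
    fine_invalid = ndimage.zoom(
        invalid.astype(np.float64), zoom, order=0, mode="nearest", grid_mode=True
    ) > 0.5
    scale = b1.voxel_size * data.shape[0] / target_shape[0]
    return B1Map(fine, scale, valid=~fine_invalid)


def _linearized_pair(sa, sb, alpha_a, alpha_b):
    """Common linearization Y_i = S_i/sin(a_i), X_i = S_i/tan(a_i); slope and
    intercept of the two-point line."""
    ya = sa / np.sin(alpha_a)
    yb = sb / np.sin(alpha_b)
    xa = sa / np.tan(alpha_a)
    xb = sb / np.tan(alpha_b)
    dx = xb - xa
    ok = dx != 0
    slope = np.full(sa.shape, np.nan)
    np.divide(yb - ya, dx, out=slope, where=ok)
    intercept = ya - slope * xa
    return slope, intercept, ok


def fit_despot1(
    sa: SignalVolume, sb: SignalVolume, b1: Optional[B1Map] = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-point variable-flip-angle T1/M0 fit from two SPGR volumes.

    The SPGR equation linearizes to Y = E1 X + M0 (1 - E1) with
    Y = S/sin(a), X = S/tan(a); the slope through the two flip-angle points
    is E1, so T1 = -TR / ln(slope) and M0 = intercept / (1 - slope). The
    effective angles are B1-corrected when a transmit map is supplied.

    Returns (t1, m0, valid); voxels with slope outside (0, 1) are invalid
    (never clamped — clamping would bias group statistics).
    """
    acq_a, acq_b = sa.acquisition, sb.acquisition
    if acq_a.flip_deg == acq_b.flip_deg:
        raise ValueError("the two SPGR volumes must have distinct flip angles")
    if acq_a.tr != acq_b.tr:
        raise ValueError("the two SPGR volumes must share TR")
    tr = acq_a.tr
    rel = b1.data if b1 is not None else 1.0
    alpha_a = np.deg2rad(acq_a.flip_deg) * rel
    alpha_b = np.deg2rad(acq_b.flip_deg) * rel

    slope, intercept, ok = _linearized_pair(sa.data, sb.data, alpha_a, alpha_b)
    valid = ok & np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
    if b1 is not None and b1.valid is not None:
        valid &= b1.valid

    t1 = np.full(slope.shape, np.nan)
    t1[valid] = -tr / np.log(slope[valid])
    m0 = np.full(slope.shape, np.nan)
    m0[valid] = intercept[valid] / (1.0 - slope[valid])
    valid = valid & np.isfinite(t1) & np.isfinite(m0) & (t1 > 0)
    return t1, m0, valid


def fit_despot2(
    sa: SignalVolume,
    sb: SignalVolume,
    t1: np.ndarray,
    b1: Optional[B1Map] = None,
    t1_valid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-point T2 fit from two balanced SSFP volumes, given T1.

    The on-resonance bSSFP equation linearizes with the same Y/X
    transformation to slope m = (E1 - E2) / (1 - E1 E2), hence
    E2 = (E1 - m) / (1 - m E1) and T2 = -TR / ln(E2). Voxels with
    E2 outside (0, 1) (including the m -> E1, T2 -> infinity boundary),
    missing T1, or an invalid transmit factor are flagged invalid.

    Returns (t2, valid).
    """
    acq_a, acq_b = sa.acquisition, sb.acquisition
    if acq_a.flip_deg == acq_b.flip_deg:
        raise ValueError("the two bSSFP volumes must have distinct flip angles")
    if acq_a.tr != acq_b.tr:
        raise ValueError("the two bSSFP volumes must share TR")
    tr = acq_a.tr
    rel = b1.data if b1 is not None else 1.0
    alpha_a = np.deg2rad(acq_a.flip_deg) * rel
    alpha_b = np.deg2rad(acq_b.flip_deg) * rel

    slope, _, ok = _linearized_pair(sa.data, sb.data, alpha_a, alpha_b)
    t1 = np.asarray(t1, dtype=np.float64)
    valid = ok & np.isfinite(slope) & np.isfinite(t1) & (t1 > 0)
    if t1_valid is not None:
        valid &= t1_valid
    if b1 is not None and b1.valid is not None:
        valid &= b1.valid

    e1 = np.full(slope.shape, np.nan)
    np.exp(np.divide(-tr, t1, out=np.full(slope.shape, np.nan), where=valid),
           out=e1, where=valid)
    denom = 1.0 - slope * e1
    e2 = np.full(slope.shape, np.nan)
    np.divide(e1 - slope, denom, out=e2, where=valid & (denom != 0))
    valid &= np.isfinite(e2) & (e2 > 0.0) & (e2 < 1.0)
    t2 = np.full(slope.shape, np.nan)
    t2[valid] = -tr / np.log(e2[valid])
    valid = valid & np.isfinite(t2) & (t2 > 0)
    return t2, valid


def compute_mtr(s0: SignalVolume, ssat: SignalVolume) -> tuple[np.ndarray, np.ndarray]:
    """Magnetization transfer ratio, percent signal drop under saturation.

    MTR = (S0 - Ssat) / S0 * 100. Voxels with S0 <= 0 or non-finite inputs
    are flagged invalid. Returns (mtr, valid).
    """
    a = np.asarray(s0.data, dtype=np.float64)
    b = np.asarray(ssat.data, dtype=np.float64)
    valid = np.isfinite(a) & np.isfinite(b) & (a > 0)
    mtr = np.full(a.shape, np.nan)
    np.divide(a - b, a, out=mtr, where=valid)
    mtr *= 100.0
    return mtr, valid


def banding_exclusion_mask(
    bssfp_a: SignalVolume,
    bssfp_b: SignalVolume,
    t1: np.ndarray,
    t2: np.ndarray,
    t2_valid: np.ndarray,
    m0_reference: np.ndarray,
    b1: Optional[B1Map] = None,
    tol: float = 0.2,
    use_metadata: bool = True,
) -> np.ndarray:
    """Exclusion mask for off-resonance banding in the T2 map.

    A two-point fit is exact by construction, so banding cannot be detected
    from its own residual. Instead, the bSSFP line's intercept implies an
    independent proton density, M0_bssfp = intercept (1 - E1 E2) / (1 - E1);
    where off-resonance corrupts the signals this disagrees with the M0
    fitted from the spoiled acquisition. Voxels with relative disagreement
    above ``tol``, voxels with an invalid T2 fit, and (when present and
    ``use_metadata``) any injected defect region recorded in the volume
    metadata are excluded from downstream statistics.
    """
    rel = b1.data if b1 is not None else 1.0
    alpha_a = np.deg2rad(bssfp_a.acquisition.flip_deg) * rel
    alpha_b = np.deg2rad(bssfp_b.acquisition.flip_deg) * rel
    _, intercept, _ = _linearized_pair(bssfp_a.data, bssfp_b.data, alpha_a, alpha_b)

    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    m0_reference = np.asarray(m0_reference, dtype=np.float64)
    tr = bssfp_a.acquisition.tr

    comparable = (
        t2_valid & np.isfinite(intercept) & np.isfinite(m0_reference)
        & (m0_reference > 0) & np.isfinite(t1) & (t1 > 0)
    )
    e1 = np.exp(np.divide(-tr, t1, out=np.full(t1.shape, np.inf), where=t1 > 0))
    e2 = np.exp(np.divide(-tr, t2, out=np.full(t2.shape, np.inf), where=t2 > 0))
    m0_bssfp = np.full(t1.shape, np.nan)
    np.divide(intercept * (1.0 - e1 * e2), 1.0 - e1, out=m0_bssfp,
              where=comparable & (e1 < 1.0))
    mismatch = np.full(t1.shape, np.nan)
    np.divide(np.abs(m0_bssfp - m0_reference), m0_reference, out=mismatch,
              where=comparable)

    excluded = ~t2_valid | (comparable & (mismatch > tol))
    if use_metadata:
        for vol in (bssfp_a, bssfp_b):
            if vol.defect_mask is not None:
                excluded |= vol.defect_mask
    return excluded


def fit_qmaps(
    signals: dict[str, SignalVolume],
    b1: Optional[B1Map] = None,
    banding_tol: float = 0.2,
) -> QMaps:
    """Run the full inversion chain on a phantom-style signal dictionary.

    Expects keys spgr_low/spgr_high, bssfp_low/bssfp_high, mt_off/mt_on and,
    when ``b1`` is None, dam_1/dam_2 from which the transmit map is computed.
    """
    if b1 is None:
        b1 = compute_b1(signals["dam_1"], signals["dam_2"],
                        nominal_deg=signals["dam_1"].acquisition.flip_deg)
    t1, m0, v1 = fit_despot1(signals["spgr_low"], signals["spgr_high"], b1)
    t2, v2 = fit_despot2(signals["bssfp_low"], signals["bssfp_high"], t1, b1,
                         t1_valid=v1)
    mtr, vm = compute_mtr(signals["mt_off"], signals["mt_on"])
    excluded = banding_exclusion_mask(
        signals["bssfp_low"], signals["bssfp_high"], t1, t2, v2, m0, b1,
        tol=banding_tol,
    )
    return QMaps(
        t1=t1, t2=t2, m0=m0, mtr=mtr,
        valid={"t1": v1, "t2": v2, "m0": v1, "mtr": vm},
        excluded=excluded,
    )
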