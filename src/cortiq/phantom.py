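"""Synthetic fixed-hemisphere phantom with known ground truth.

This module generates the digital specimen on which the rest of the package
operates: a folded cortical ribbon wrapped around a white-matter core,
immersed in formalin, with

* per-tissue quantitative parameters (T1, T2, M0, MT saturation fraction
  delta, myelin content) drawn from a configurable tissue table,
* a pial-to-WM laminar myelin gradient inside the cortex, coupled to the
  relaxation parameters through rate-linear relations calibrated on the
  normal-appearing-cortex and cortical-lesion rows of the tissue table,
* type III subpial demyelinating lesions and focal WM lesions,
* a smooth low-order polynomial B1 transmit field,
* closed-form steady-state forward models (SPGR, balanced SSFP, the
  MT-weighted SPGR pair and the double-angle B1 pair),
* Rician magnitude noise, and
* a synthetic chromogen-stained slide renderer (red-brown myelin fibers on a
  light-blue counterstain background).

Every stochastic step is driven by child streams spawned from a single seed,
so a (spec, seed) pair reproduces the dataset bit for bit.

Coordinate convention: 0-based voxel indices, axis order (x, y, z), world
position = index * voxel_size (mm). Coronal planes are planes of constant y.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "Tissue",
    "TissueRow",
    "PhantomSpec",
    "LesionSpec",
    "BandingDefectSpec",
    "LabelVolume",
    "ParameterMaps",
    "AcquisitionParams",
    "B1Map",
    "SignalVolume",
    "SlideImage",
    "RateCouplings",
    "default_tissue_table",
    "calibrate_couplings",
    "build_geometry",
    "assign_tissue_parameters",
    "implant_lesions",
    "auto_lesions",
    "find_subpial_seed",
    "generate_b1_field",
    "simulate_spgr",
    "simulate_bssfp",
    "simulate_mt_pair",
    "simulate_dam_pair",
    "add_rician_noise",
    "render_histology_slide",
    "generate_phantom",
    "PhantomDataset",
    "SPGR_LOW",
    "SPGR_HIGH",
    "BSSFP_LOW",
    "BSSFP_HIGH",
    "MT_OFF",
    "MT_ON",
]


class Tissue(IntEnum):
    """Integer labels of the phantom tissue partition."""

    FORMALIN = 0
    WM = 1
    CORTEX = 2
    SUBCORTICAL_GM = 3
    CORTICAL_LESION = 4
    WM_LESION = 5


#: Tissue classes that count as white matter for depth/boundary purposes.
WM_LIKE = (Tissue.WM, Tissue.WM_LESION, Tissue.SUBCORTICAL_GM)
#: Tissue classes forming the cortical ribbon.
CORTICAL = (Tissue.CORTEX, Tissue.CORTICAL_LESION)


@dataclass(frozen=True)
class TissueRow:
    """Mean/SD of the quantitative parameters of one tissue class.

    Units: T1, T2 in ms; M0 in relative units; delta is the MT saturation
    fraction (MTR/100, dimensionless in [0, 1]); myelin in % area.
    """

    t1: float
    t1_sd: float
    t2: float
    t2_sd: float
    m0: float
    m0_sd: float
    delta: float
    delta_sd: float
    myelin: float
    myelin_sd: float

    def __post_init__(self):
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("T1 and T2 must be positive")
        if self.t2 > self.t1:
            raise ValueError("T2 must not exceed T1 for a tissue class")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("saturation fraction delta must lie in [0, 1]")
        if not 0.0 <= self.myelin <= 100.0:
            raise ValueError("myelin content must lie in [0, 100] %")

    def zero_sd(self) -> "TissueRow":
        return dataclasses.replace(
            self, t1_sd=0.0, t2_sd=0.0, m0_sd=0.0, delta_sd=0.0, myelin_sd=0.0
        )


def default_tissue_table() -> dict[str, TissueRow]:
    """Default tissue table for the fixed post-mortem MS hemisphere phantom.

    The four MS tissue classes (normal-appearing cortex, cortical lesion,
    normal-appearing white matter, WM lesion) carry the published fixed-tissue
    values this phantom is designed to emulate. The formalin bath has no
    published quantitative row; its values are a package choice of plausible
    fixed-formalin numbers (long T1/T2, no macromolecular pool, no myelin).
    Subcortical grey matter reuses the cortical row.
    """
    nac = TissueRow(209, 27, 64, 11, 3797, 114, 0.0747, 0.0126, 7.96, 6.69)
    cl = TissueRow(236, 26, 91, 22, 3835, 86, 0.0709, 0.0109, 1.96, 2.55)
    nawm = TissueRow(196, 18, 56, 13, 3467, 88, 0.1282, 0.0090, 74.18, 4.70)
    wml = TissueRow(380, 88, 121, 27, 4005, 111, 0.0616, 0.0279, 27.55, 14.32)
    formalin = TissueRow(2200, 50, 800, 30, 5000, 100, 0.005, 0.002, 0.0, 0.0)
    return {
        "formalin": formalin,
        "wm": nawm,
        "cortex": nac,
        "subcortical_gm": nac,
        "cortical_lesion": cl,
        "wm_lesion": wml,
    }


#: Mapping from Tissue label to tissue-table key.
TISSUE_KEY = {
    Tissue.FORMALIN: "formalin",
    Tissue.WM: "wm",
    Tissue.CORTEX: "cortex",
    Tissue.SUBCORTICAL_GM: "subcortical_gm",
    Tissue.CORTICAL_LESION: "cortical_lesion",
    Tissue.WM_LESION: "wm_lesion",
}


@dataclass(frozen=True)
class LesionSpec:
    """One lesion to implant.

    kind
        ``"subpial_typeIII"`` — tangential demyelination of the superficial
        cortical laminae, seeded at the pial surface: cortex voxels within
        ``tangential_radius`` (mm) of the pial seed point whose fractional
        depth is below ``depth_fraction`` are relabeled and re-parameterized
        from ``target_tissue_row``.
        ``"wm_focal"`` — a spherical focal lesion inside white matter.
    center
        Voxel coordinate (x, y, z) in or near the required tissue.
    """

    kind: str
    center: tuple[int, int, int]
    tangential_radius: float
    depth_fraction: float = 0.5
    target_tissue_row: str = ""

    def __post_init__(self):
        if self.kind not in ("subpial_typeIII", "wm_focal"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.tangential_radius <= 0:
            raise ValueError("tangential_radius must be positive")
        if not 0.0 < self.depth_fraction <= 1.0:
            raise ValueError("depth_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class BandingDefectSpec:
    """Off-resonance banding stand-in for the balanced SSFP acquisitions.

    A spherical region (voxel center, radius in mm) whose two bSSFP signals
    are multiplied by ``factors``, corrupting the two-point T2 fit there. The
    region is recorded in the signal metadata so exclusion-mask bookkeeping
    can be verified exactly.
    """

    center: tuple[int, int, int]
    radius_mm: float
    factors: tuple[float, float] = (0.6, 0.4)


@dataclass
class PhantomSpec:
    """Full description of a synthetic specimen.

    The defaults are the study conditions the package emulates: 0.35 mm
    isotropic voxels, a cortical ribbon 8 voxels (2.8 mm) thick, +/-20 % B1
    transmit variation, and the default tissue table. ``lesion_specs=None``
    places two subpial lesions and one focal WM lesion automatically at
    geometrically valid sites.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    voxel_size: float = 0.35
    tissue_table: dict[str, TissueRow] = field(default_factory=default_tissue_table)
    lesion_specs: Optional[list[LesionSpec]] = None
    b1_amplitude: float = 0.2
    noise_sigma: float = 5.0
    seed: int = 0
    # geometry
    wm_radius_frac: float = 0.33
    cortical_thickness_vox: int = 8
    fold_amplitude_vox: float = 3.0
    fold_order: tuple[int, int] = (3, 2)
    subcortical_radius_frac: float = 0.10
    # laminar myelin field
    laminar_profile: str = "linear"  # "linear" | "sigmoid" | "none"
    laminar_contrast: float = 0.7
    # histology rendering
    upsample_factor: int = 10
    banding_defect: Optional[BandingDefectSpec] = None

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if not 0.0 <= self.b1_amplitude <= 0.5:
            raise ValueError("b1_amplitude must lie in [0, 0.5]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.laminar_profile not in ("linear", "sigmoid", "none"):
            raise ValueError(f"unknown laminar_profile {self.laminar_profile!r}")
        if not 0.0 <= self.laminar_contrast <= 1.0:
            raise ValueError("laminar_contrast must lie in [0, 1]")

    def noiseless(self) -> "PhantomSpec":
        """A copy with every source of parameter/signal variance removed.

        Tissue SDs are zeroed, the laminar gradient is flattened and the
        measurement noise is switched off; the B1 field is retained (it is
        deterministic and is corrected exactly downstream).
        """
        table = {k: v.zero_sd() for k, v in self.tissue_table.items()}
        return dataclasses.replace(
            self,
            tissue_table=table,
            noise_sigma=0.0,
            laminar_profile="none",
        )


@dataclass
class LabelVolume:
    """Integer tissue partition on the phantom grid."""

    data: np.ndarray  # int16, shape = grid_shape
    voxel_size: float

    def mask(self, *tissues: Tissue) -> np.ndarray:
        out = np.zeros(self.data.shape, dtype=bool)
        for t in tissues:
            out |= self.data == int(t)
        return out

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.voxel_size)


@dataclass
class ParameterMaps:
    """Voxel-wise quantitative ground truth, co-registered on the label grid.

    t1, t2 in ms; m0 in relative units; delta = saturation fraction in
    [0, 1]; myelin in % area.
    """

    t1: np.ndarray
    t2: np.ndarray
    m0: np.ndarray
    delta: np.ndarray
    myelin: np.ndarray
    voxel_size: float

    def validate(self) -> None:
        if np.any(self.t1 <= 0) or np.any(self.t2 <= 0):
            raise ValueError("relaxation times must be positive everywhere")
        if np.any(self.t2 >= self.t1):
            raise ValueError("T2 must stay below T1 everywhere")
        if np.any((self.delta < 0) | (self.delta > 1)):
            raise ValueError("delta out of [0, 1]")
        if np.any((self.myelin < 0) | (self.myelin > 100)):
            raise ValueError("myelin out of [0, 100]")

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(
            self.t1.copy(), self.t2.copy(), self.m0.copy(),
            self.delta.copy(), self.myelin.copy(), self.voxel_size,
        )


@dataclass(frozen=True)
class AcquisitionParams:
    """Acquisition metadata of one simulated magnitude volume."""

    sequence: str  # "SPGR" | "bSSFP" | "SPGR_MT" | "DAM"
    tr: float  # ms
    te: float  # ms
    flip_deg: float
    mt_saturation: bool = False

    def __post_init__(self):
        if not 0.0 < self.flip_deg < 180.0:
            raise ValueError("flip angle must lie in (0, 180) degrees")
        if self.te >= self.tr:
            raise ValueError("TE must be shorter than TR")


# The protocol of the emulated study: two spoiled gradient echo volumes for
# T1/M0, two balanced SSFP volumes for T2, a proton-density-weighted SPGR
# pair (saturation off/on) for MTR, and a 20 deg double-angle pair for B1.
SPGR_LOW = AcquisitionParams("SPGR", tr=7.7, te=3.35, flip_deg=4.0)
SPGR_HIGH = AcquisitionParams("SPGR", tr=7.7, te=3.35, flip_deg=22.0)
BSSFP_LOW = AcquisitionParams("bSSFP", tr=7.7, te=3.84, flip_deg=20.0)
BSSFP_HIGH = AcquisitionParams("bSSFP", tr=7.7, te=3.84, flip_deg=70.0)
MT_OFF = AcquisitionParams("SPGR_MT", tr=25.0, te=4.09, flip_deg=25.0, mt_saturation=False)
MT_ON = AcquisitionParams("SPGR_MT", tr=25.0, te=4.09, flip_deg=25.0, mt_saturation=True)


@dataclass
class B1Map:
    """Multiplicative transmit-field map: actual flip = data * nominal flip."""

    data: np.ndarray
    voxel_size: float
    valid: Optional[np.ndarray] = None  # None means valid everywhere


@dataclass
class SignalVolume:
    """One magnitude acquisition plus its metadata."""

    data: np.ndarray
    acquisition: AcquisitionParams
    voxel_size: float
    noise_sigma: float = 0.0
    defect_mask: Optional[np.ndarray] = None  # injected banding region


@dataclass
class SlideImage:
    """8-bit RGB stained-slide raster; pixel_size in micrometres."""

    data: np.ndarray  # uint8, (H, W, 3)
    pixel_size_um: float

    def __post_init__(self):
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError("slide must be an RGB raster (H, W, 3)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def build_geometry(spec: PhantomSpec) -> LabelVolume:
    """Build the folded-hemisphere tissue partition.

    A white-matter core of radius ``wm_radius_frac * min(grid)`` voxels is
    wrapped by a cortical shell ``cortical_thickness_vox`` voxels thick; the
    WM/cortex and pial boundaries are perturbed by a low-order sinusoid in the
    spherical angles, producing reproducible gyri and sulci with a radially
    constant shell thickness. Everything outside the pial surface is
    formalin; a small central sphere is labeled subcortical grey matter.

    Deterministic given ``spec.seed`` (the fold phases are drawn from a child
    stream of the spec seed).
    """
    shape = tuple(spec.grid_shape)
    if min(shape) < 32:
        raise ValueError("grid_shape must be at least 32 voxels per axis")
    if not 6 <= spec.cortical_thickness_vox <= 10:
        raise ValueError("cortical thickness must be 6-10 voxels")

    wm_radius = spec.wm_radius_frac * min(shape)
    outer = wm_radius + spec.fold_amplitude_vox + spec.cortical_thickness_vox
    if outer + 1.5 > min(shape) / 2.0:
        raise ValueError(
            f"grid too small: shell extends to {outer:.1f} voxels from center "
            f"but half the smallest axis is {min(shape) / 2.0:.1f}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    phase_t, phase_p = rng.uniform(0.0, 2.0 * np.pi, size=2)

    idx = np.indices(shape, dtype=np.float64)
    center = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    x = idx[0] - center[0]
    y = idx[1] - center[1]
    z = idx[2] - center[2]
    r = np.sqrt(x * x + y * y + z * z)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, z / np.maximum(r, 1e-12), 1.0), -1, 1))
    phi = np.arctan2(y, x)

    k_t, k_p = spec.fold_order
    fold = spec.fold_amplitude_vox * np.sin(k_t * theta + phase_t) * np.cos(k_p * phi + phase_p)
    r_wm = wm_radius + fold

    labels = np.zeros(shape, dtype=np.int16)  # formalin
    labels[r <= r_wm] = int(Tissue.WM)
    cortex = (r > r_wm) & (r <= r_wm + spec.cortical_thickness_vox)
    labels[cortex] = int(Tissue.CORTEX)

    sub_r = spec.subcortical_radius_frac * min(shape)
    labels[r <= sub_r] = int(Tissue.SUBCORTICAL_GM)

    return LabelVolume(labels, spec.voxel_size)


# ---------------------------------------------------------------------------
# myelin -> parameter couplings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateCouplings:
    """Monotone couplings between myelin content m (% area) and parameters.

    Relaxation is linear in rate, 1/T = a + kappa * m, which yields the
    strongly non-linear time-versus-content relation characteristic of fixed
    cortical tissue (relaxation times blow up as m -> 0). The saturation
    fraction is linear, delta = a3 + kappa3 * m, and proton density declines
    linearly, M0 = a4 - kappa4 * m. All four kappas are calibrated from two
    anchor points — the cortical-lesion and normal-appearing-cortex rows of
    the tissue table — and must come out positive; a non-positive kappa means
    the table does not support a monotone myelin coupling and is an error.
    """

    a1: float
    k1: float
    a2: float
    k2: float
    a3: float
    k3: float
    a4: float
    k4: float

    def t1(self, m):
        return 1.0 / (self.a1 + self.k1 * np.asarray(m, dtype=np.float64))

    def t2(self, m):
        return 1.0 / (self.a2 + self.k2 * np.asarray(m, dtype=np.float64))

    def delta(self, m):
        return np.clip(self.a3 + self.k3 * np.asarray(m, dtype=np.float64), 0.0, 1.0)

    def m0(self, m):
        return self.a4 - self.k4 * np.asarray(m, dtype=np.float64)


def calibrate_couplings(nac: TissueRow, cl: TissueRow) -> RateCouplings:
    """Two-point calibration of the myelin couplings.

    Solves each linear relation so that m = cl.myelin maps exactly onto the
    cortical-lesion row and m = nac.myelin onto the normal-appearing-cortex
    row.
    """
    dm = nac.myelin - cl.myelin
    if dm == 0:
        raise ValueError("tissue rows have identical myelin means; cannot calibrate")
    k1 = (1.0 / nac.t1 - 1.0 / cl.t1) / dm
    k2 = (1.0 / nac.t2 - 1.0 / cl.t2) / dm
    k3 = (nac.delta - cl.delta) / dm
    k4 = (cl.m0 - nac.m0) / dm
    if min(k1, k2, k3, k4) <= 0:
        raise ValueError(
            "non-monotone calibration: all couplings must be positive, got "
            f"k1={k1:.3g}, k2={k2:.3g}, k3={k3:.3g}, k4={k4:.3g}"
        )
    a1 = 1.0 / cl.t1 - k1 * cl.myelin
    a2 = 1.0 / cl.t2 - k2 * cl.myelin
    a3 = cl.delta - k3 * cl.myelin
    a4 = cl.m0 + k4 * cl.myelin
    return RateCouplings(a1, k1, a2, k2, a3, k3, a4, k4)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0.0:
        return np.full(size, float(mean))
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return _sstats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _myelin_draw(rng, mean, sd, size):
    """Moment-matched gamma draw of myelin content (% area).

    Myelin SDs are of the same order as the means, so a 0-truncated Gaussian
    would bias the mean upward appreciably; a gamma with the same first two
    moments lives on positive support and reproduces mean and SD exactly.
    """
    if sd == 0.0 or mean == 0.0:
        return np.full(size, float(mean))
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return np.clip(_sstats.gamma.rvs(shape, scale=scale, size=size, random_state=rng),
                   0.0, 100.0)


def _myelin_quantiles(mean, sd, n):
    """Deterministic gamma quantile ladder (midpoint plotting positions)."""
    if sd == 0.0 or mean == 0.0 or n == 0:
        return np.full(n, float(mean))
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    q = (np.arange(n) + 0.5) / n
    return np.clip(_sstats.gamma.ppf(q, shape, scale=scale), 0.0, 100.0)


def _draw_row(rng, row: TissueRow, n: int):
    t1 = _truncated_normal(rng, row.t1, row.t1_sd, 1.0, np.inf, n)
    t2 = _truncated_normal(rng, row.t2, row.t2_sd, 0.5, np.inf, n)
    t2 = np.minimum(t2, 0.95 * t1)  # enforce T2 < T1 voxel-wise
    m0 = _truncated_normal(rng, row.m0, row.m0_sd, 1e-6, np.inf, n)
    delta = _truncated_normal(rng, row.delta, row.delta_sd, 0.0, 1.0, n)
    myelin = _myelin_draw(rng, row.myelin, row.myelin_sd, n)
    return t1, t2, m0, delta, myelin


def assign_tissue_parameters(
    labels: LabelVolume,
    spec: PhantomSpec,
    seed: Optional[int] = None,
    depth: Optional[np.ndarray] = None,
) -> ParameterMaps:
    """Populate voxel-wise ground-truth parameter maps.

    Non-cortical classes draw (T1, T2, M0, delta) from truncated Gaussians
    around their tissue-table rows and myelin from a moment-matched gamma.
    Cortical voxels instead receive a myelin field with a pial->WM laminar
    gradient, rank-mapped onto the gamma marginal of the cortex row so the
    cortex-wide mean/SD match the row, and their remaining parameters follow
    deterministically from the rate-linear couplings — this is what makes the
    cortical relation between relaxation time and myelin content strictly
    monotone and non-linear.

    ``depth`` is the fractional cortical depth field; it is computed on the
    fly when not supplied.

    Parameters are assigned for the *cortex* class only here; lesions are
    re-parameterized by :func:`implant_lesions`.
    """
    table = spec.tissue_table
    for lab in np.unique(labels.data):
        key = TISSUE_KEY[Tissue(int(lab))]
        if key not in table:
            raise ValueError(f"tissue_table has no row for label {key!r}")

    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))

    shape = labels.data.shape
    t1 = np.empty(shape, dtype=np.float64)
    t2 = np.empty(shape, dtype=np.float64)
    m0 = np.empty(shape, dtype=np.float64)
    delta = np.empty(shape, dtype=np.float64)
    myelin = np.empty(shape, dtype=np.float64)

    for tissue in Tissue:
        mask = labels.data == int(tissue)
        n = int(mask.sum())
        if n == 0 or tissue in CORTICAL:
            continue
        row = table[TISSUE_KEY[tissue]]
        vt1, vt2, vm0, vd, vm = _draw_row(rng, row, n)
        t1[mask], t2[mask], m0[mask], delta[mask], myelin[mask] = vt1, vt2, vm0, vd, vm

    cmask = labels.mask(*CORTICAL)
    n_ctx = int(cmask.sum())
    if n_ctx:
        row = table["cortex"]
        if depth is None:
            from .cortex import depth_field  # local import avoids a cycle

            depth = depth_field(labels)
        d = depth[cmask]
        m = _laminar_myelin(rng, d, row, spec)
        coup = calibrate_couplings(table["cortex"], table["cortical_lesion"])
        myelin[cmask] = m
        t1[cmask] = coup.t1(m)
        t2[cmask] = coup.t2(m)
        delta[cmask] = coup.delta(m)
        m0[cmask] = coup.m0(m)

    maps = ParameterMaps(t1, t2, m0, delta, myelin, labels.voxel_size)
    maps.validate()
    return maps


def _laminar_myelin(rng, d: np.ndarray, row: TissueRow, spec: PhantomSpec) -> np.ndarray:
    """Cortical myelin field: laminar gradient rank-mapped onto the row marginal.

    A latent score mixes the depth profile (superficial laminae least
    myelinated) with voxel noise, weighted by ``laminar_contrast``; the
    scores' ranks are then mapped onto the gamma quantile ladder matched to
    the row's mean/SD. Any strictly monotone profile therefore yields a field
    whose marginal moments match the row while myelin increases, on average,
    with depth.
    """
    n = d.size
    if spec.laminar_profile == "none" or row.myelin_sd == 0.0:
        return np.full(n, row.myelin)
    if spec.laminar_profile == "linear":
        prof = d
    else:  # sigmoid
        prof = 1.0 / (1.0 + np.exp(-8.0 * (d - 0.5)))
    prof = (prof - prof.mean()) / max(prof.std(), 1e-12)
    c = spec.laminar_contrast
    score = c * prof + (1.0 - c) * rng.standard_normal(n)
    order = np.argsort(score, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    ladder = _myelin_quantiles(row.myelin, row.myelin_sd, n)
    return ladder[ranks]


# ---------------------------------------------------------------------------
# lesions
# ---------------------------------------------------------------------------

def find_subpial_seed(
    labels: LabelVolume, depth: np.ndarray, center: Sequence[int], radius_mm: float
) -> tuple[int, int, int]:
    """Pial seed voxel of a subpial lesion: the shallowest cortical voxel
    (fractional depth <= 0.2 preferred, i.e. the voxelized pial layer)
    nearest to ``center`` within the lesion radius. Deterministic; raises if
    no cortical voxel is in range."""
    cmask = labels.mask(*CORTICAL)
    if not cmask[tuple(center)]:
        raise ValueError(f"subpial lesion center {tuple(center)} is not in cortex")
    coords = np.argwhere(cmask)
    dist = np.linalg.norm((coords - np.asarray(center)) * labels.voxel_size, axis=1)
    in_range = dist <= radius_mm
    if not in_range.any():
        raise ValueError("no cortical voxel within tangential_radius of center")
    cand = coords[in_range]
    cand_depth = depth[tuple(cand.T)]
    cand_dist = dist[in_range]
    pial = cand_depth <= 0.2
    if pial.any():
        cand, cand_depth, cand_dist = cand[pial], cand_depth[pial], cand_dist[pial]
        best = np.lexsort((cand_depth, cand_dist))[0]
    else:
        best = np.lexsort((cand_dist, cand_depth))[0]
    return tuple(int(v) for v in cand[best])


def implant_lesions(
    labels: LabelVolume,
    maps: ParameterMaps,
    spec: PhantomSpec,
    depth: np.ndarray,
    seed: Optional[int] = None,
) -> tuple[LabelVolume, ParameterMaps]:
    """Relabel and re-parameterize lesion voxels; returns modified copies.

    Subpial (type III) lesions: cortical voxels within ``tangential_radius``
    mm of the pial seed point and with fractional depth strictly below
    ``depth_fraction`` become cortical lesion; their myelin is redrawn from
    the lesion row's gamma marginal and the remaining parameters follow from
    the rate couplings, so lesions stay on the cortical myelin-parameter
    relation (demyelination, not a separate physics).

    Focal WM lesions: WM voxels inside the sphere of ``tangential_radius`` mm
    are relabeled and redrawn independently from the WM-lesion row — WM
    lesions do not lie on the cortical coupling.
    """
    if spec.lesion_specs is None:
        lesions: list[LesionSpec] = []
    else:
        lesions = list(spec.lesion_specs)
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 37]))

    labels = labels.copy()
    maps = maps.copy()
    table = spec.tissue_table
    coup = calibrate_couplings(table["cortex"], table["cortical_lesion"])
    vox = labels.voxel_size
    idx = np.indices(labels.data.shape).astype(np.float64)

    for les in lesions:
        if les.kind == "subpial_typeIII":
            seed_vox = find_subpial_seed(labels, depth, les.center, les.tangential_radius)
            dist = np.sqrt(sum((idx[i] - seed_vox[i]) ** 2 for i in range(3))) * vox
            sel = (
                labels.mask(Tissue.CORTEX)
                & (dist <= les.tangential_radius)
                & (depth < les.depth_fraction)
            )
            row = table[les.target_tissue_row or "cortical_lesion"]
            n = int(sel.sum())
            m = _myelin_draw(rng, row.myelin, row.myelin_sd, n)
            labels.data[sel] = int(Tissue.CORTICAL_LESION)
            maps.myelin[sel] = m
            maps.t1[sel] = coup.t1(m)
            maps.t2[sel] = coup.t2(m)
            maps.delta[sel] = coup.delta(m)
            maps.m0[sel] = coup.m0(m)
        else:  # wm_focal
            if labels.data[tuple(les.center)] != int(Tissue.WM):
                raise ValueError(
                    f"wm_focal lesion center {tuple(les.center)} is not in white matter"
                )
            dist = np.sqrt(sum((idx[i] - les.center[i]) ** 2 for i in range(3))) * vox
            sel = labels.mask(Tissue.WM) & (dist <= les.tangential_radius)
            row = table[les.target_tissue_row or "wm_lesion"]
            n = int(sel.sum())
            vt1, vt2, vm0, vd, vm = _draw_row(rng, row, n)
            labels.data[sel] = int(Tissue.WM_LESION)
            maps.t1[sel], maps.t2[sel], maps.m0[sel] = vt1, vt2, vm0
            maps.delta[sel], maps.myelin[sel] = vd, vm

    maps.validate()
    return labels, maps


def auto_lesions(
    labels: LabelVolume,
    depth: np.ndarray,
    subpial_radius_mm: float = 6.0,
    depth_fraction: float = 0.5,
    wm_radius_mm: float = 2.5,
) -> list[LesionSpec]:
    """Place the default lesion set at geometrically valid sites.

    Two subpial lesions are seeded at the pial voxels furthest along +x and
    -x, one focal WM lesion at the WM voxel deepest inside WM in the +y half.
    The WM lesion radius is shrunk to fit entirely inside WM when the core is
    small; it is omitted (with a 2-voxel floor) when no focal lesion fits.
    """
    from scipy import ndimage

    pial = labels.mask(*CORTICAL) & (depth <= 0.2)
    coords = np.argwhere(pial)
    if coords.size == 0:
        raise ValueError("no pial cortical voxels found")
    c_plus = tuple(int(v) for v in coords[np.argmax(coords[:, 0])])
    c_minus = tuple(int(v) for v in coords[np.argmin(coords[:, 0])])
    lesions = [
        LesionSpec("subpial_typeIII", c_plus, subpial_radius_mm, depth_fraction),
        LesionSpec("subpial_typeIII", c_minus, subpial_radius_mm, depth_fraction),
    ]

    vox = labels.voxel_size
    wm = labels.mask(Tissue.WM)
    inner = ndimage.distance_transform_edt(wm, sampling=vox)
    half = np.argwhere(inner > 0)
    plus_y = half[half[:, 1] >= labels.data.shape[1] // 2]
    if plus_y.size:
        best = plus_y[np.argmax(inner[tuple(plus_y.T)])]
        r_fit = min(wm_radius_mm, float(inner[tuple(best)]) - vox)
        if r_fit >= 2 * vox:
            lesions.append(LesionSpec("wm_focal", tuple(int(v) for v in best), r_fit))
    return lesions


# ---------------------------------------------------------------------------
# B1 transmit field
# ---------------------------------------------------------------------------

def generate_b1_field(spec: PhantomSpec) -> B1Map:
    """Smooth low-order polynomial transmit field centered at 1.0.

    A random quadratic in grid coordinates normalized to [-1, 1]^3 is scaled
    to unit max deviation, so the field range is exactly
    [1 - amplitude, 1 + amplitude]; amplitude 0 gives a uniform field.
    Deterministic given ``spec.seed``.
    """
    shape = tuple(spec.grid_shape)
    amp = spec.b1_amplitude
    if amp == 0.0:
        return B1Map(np.ones(shape, dtype=np.float64), spec.voxel_size)
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 41]))
    coeffs = rng.standard_normal(10)
    axes = [
        np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape
    ]
    u, v, w = np.meshgrid(*axes, indexing="ij")
    poly = (
        coeffs[0]
        + coeffs[1] * u + coeffs[2] * v + coeffs[3] * w
        + coeffs[4] * u * v + coeffs[5] * u * w + coeffs[6] * v * w
        + coeffs[7] * u * u + coeffs[8] * v * v + coeffs[9] * w * w
    )
    poly -= poly.mean()
    poly /= np.max(np.abs(poly))
    return B1Map(1.0 + amp * poly, spec.voxel_size)


# ---------------------------------------------------------------------------
# forward signal models
# ---------------------------------------------------------------------------

def spgr_signal(t1, m0, flip_deg, tr, b1=1.0, delta=None):
    """Closed-form steady-state spoiled gradient echo magnitude.

    S = M0 sin(a) (1 - E1) / (1 - cos(a) E1) with a = b1 * flip and
    E1 = exp(-TR/T1); when ``delta`` is given the magnetization-transfer
    saturation multiplies the signal by (1 - delta).
    """
    t1 = np.asarray(t1, dtype=np.float64)
    alpha = np.deg2rad(flip_deg) * np.asarray(b1, dtype=np.float64)
    e1 = np.exp(-tr / t1)
    s = np.asarray(m0, dtype=np.float64) * np.sin(alpha) * (1.0 - e1) / (1.0 - np.cos(alpha) * e1)
    if delta is not None:
        s = s * (1.0 - np.asarray(delta, dtype=np.float64))
    return s


def bssfp_signal(t1, t2, m0, flip_deg, tr, b1=1.0):
    """On-resonance ideal balanced SSFP magnitude.

    S = M0 sin(a) (1 - E1) / (1 - E1 E2 - (E1 - E2) cos(a)).
    """
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    alpha = np.deg2rad(flip_deg) * np.asarray(b1, dtype=np.float64)
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    denom = 1.0 - e1 * e2 - (e1 - e2) * np.cos(alpha)
    return np.asarray(m0, dtype=np.float64) * np.sin(alpha) * (1.0 - e1) / denom


def simulate_spgr(maps: ParameterMaps, acq: AcquisitionParams, b1: B1Map) -> SignalVolume:
    """Forward-simulate one SPGR magnitude volume on the phantom grid."""
    if acq.sequence not in ("SPGR", "SPGR_MT"):
        raise ValueError(f"simulate_spgr requires an SPGR acquisition, got {acq.sequence}")
    if np.any(maps.t1 <= 0):
        raise ValueError("non-positive T1 in parameter maps")
    delta = maps.delta if acq.mt_saturation else None
    s = spgr_signal(maps.t1, maps.m0, acq.flip_deg, acq.tr, b1.data, delta)
    return SignalVolume(s, acq, maps.voxel_size)


def simulate_bssfp(
    maps: ParameterMaps,
    acq: AcquisitionParams,
    b1: B1Map,
    defect_mask: Optional[np.ndarray] = None,
    defect_factor: float = 1.0,
) -> SignalVolume:
    """Forward-simulate one balanced SSFP magnitude volume.

    ``defect_mask``/``defect_factor`` optionally inject an off-resonance
    banding stand-in: signals inside the mask are multiplied by the factor and
    the mask is recorded in the volume metadata for exclusion-mask tests.
    """
    if acq.sequence != "bSSFP":
        raise ValueError(f"simulate_bssfp requires a bSSFP acquisition, got {acq.sequence}")
    if np.any(maps.t2 >= maps.t1):
        raise ValueError("bSSFP model requires T2 < T1 everywhere")
    s = bssfp_signal(maps.t1, maps.t2, maps.m0, acq.flip_deg, acq.tr, b1.data)
    if defect_mask is not None:
        s = s.copy()
        s[defect_mask] *= defect_factor
    return SignalVolume(s, acq, maps.voxel_size, defect_mask=defect_mask)


def simulate_mt_pair(maps: ParameterMaps, b1: B1Map) -> tuple[SignalVolume, SignalVolume]:
    """Proton-density-weighted SPGR pair without and with MT saturation.

    The saturation pulse is modeled as a pure multiplicative attenuation
    (1 - delta) of the steady-state signal, so the downstream percent signal
    drop equals delta * 100 exactly in the noiseless limit.
    """
    s0 = simulate_spgr(maps, MT_OFF, b1)
    ssat = simulate_spgr(maps, MT_ON, b1)
    return s0, ssat


def simulate_dam_pair(
    b1: B1Map, prep_flip_deg: float = 20.0, scale=1.0
) -> tuple[SignalVolume, SignalVolume]:
    """Double-angle B1 mapping pair.

    The magnetization-prepared readouts give S1 = K cos(b1*a) and
    S2 = K cos(2*b1*a) with a common spatial proportionality K (``scale``);
    the ratio S2/S1 depends only on the local transmit factor. Requires
    2*b1*a < 90 deg everywhere so both signals stay positive.
    """
    theta = np.deg2rad(prep_flip_deg) * b1.data
    bad = 2.0 * theta >= np.pi / 2.0
    if bad.any():
        coords = np.argwhere(bad)[:5]
        raise ValueError(
            f"double-angle precondition violated (2*b1*alpha >= 90 deg) at "
            f"{int(bad.sum())} voxels, e.g. {[tuple(c) for c in coords]}"
        )
    acq1 = AcquisitionParams("DAM", tr=2000.0, te=15.0, flip_deg=prep_flip_deg)
    acq2 = AcquisitionParams("DAM", tr=2000.0, te=15.0, flip_deg=2 * prep_flip_deg)
    k = np.asarray(scale, dtype=np.float64)
    s1 = SignalVolume(k * np.cos(theta), acq1, b1.voxel_size)
    s2 = SignalVolume(k * np.cos(2.0 * theta), acq2, b1.voxel_size)
    return s1, s2


def add_rician_noise(signal: SignalVolume, sigma: float, seed: int) -> SignalVolume:
    """Rician magnitude noise: S' = sqrt((S + n1)^2 + n2^2), n ~ N(0, sigma^2).

    Signal averaging of the emulated protocol is folded into the single
    effective sigma. ``sigma = 0`` returns the input volume unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0.0:
        return signal
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 53]))
    n1 = rng.normal(0.0, sigma, size=signal.data.shape)
    n2 = rng.normal(0.0, sigma, size=signal.data.shape)
    noisy = np.sqrt((signal.data + n1) ** 2 + n2 ** 2)
    return SignalVolume(
        noisy, signal.acquisition, signal.voxel_size,
        noise_sigma=float(sigma), defect_mask=signal.defect_mask,
    )


# ---------------------------------------------------------------------------
# synthetic histology
# ---------------------------------------------------------------------------

#: AEC chromogen (myelin fiber) and Acid-Blue counterstain (background) colors.
FIBER_RGB = (150, 60, 50)
BACKGROUND_RGB = (160, 195, 230)


def render_histology_slide(
    content2d: np.ndarray,
    upsample_factor: int = 10,
    seed: int = 0,
    voxel_size_mm: float = 0.35,
    color_jitter: int = 12,
) -> SlideImage:
    """Render a synthetic chromogen-stained slide from a 2D myelin content map.

    Each MR-resolution block of ``factor x factor`` slide pixels is painted
    with short randomly oriented fiber strokes in the red-brown chromogen
    color until the painted-pixel count equals ``round(content/100 * f^2)``
    exactly (strokes are truncated pixel-wise at the target), over a light
    blue counterstain background. Bounded per-pixel color jitter preserves
    the red-minus-blue sign, so the rendered content is recoverable by the
    color-separation segmenter to within one block pixel.
    """
    content2d = np.asarray(content2d, dtype=np.float64)
    if content2d.ndim != 2:
        raise ValueError("content map must be 2D")
    if np.any(content2d > 100.0) or np.any(content2d < 0.0):
        raise ValueError("myelin content must lie in [0, 100] %")
    f = int(upsample_factor)
    if f < 4:
        raise ValueError("upsample_factor must be >= 4")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 67]))
    h, w = content2d.shape
    fiber = np.zeros((h * f, w * f), dtype=bool)

    for i in range(h):
        for j in range(w):
            target = int(round(content2d[i, j] / 100.0 * f * f))
            if target <= 0:
                continue
            block = np.zeros((f, f), dtype=bool)
            painted = 0
            attempts = 0
            while painted < target and attempts < 40 * f:
                attempts += 1
                r0 = rng.uniform(0, f - 1)
                c0 = rng.uniform(0, f - 1)
                ang = rng.uniform(0, np.pi)
                length = rng.uniform(0.5 * f, 1.0 * f)
                r1 = r0 + length * np.sin(ang)
                c1 = c0 + length * np.cos(ang)
                rr, cc = _line_pixels(r0, c0, r1, c1, f)
                for r, c in zip(rr, cc):
                    if not block[r, c]:
                        block[r, c] = True
                        painted += 1
                        if painted == target:
                            break
            if painted < target:  # nearly full block: fill remaining pixels
                free = np.argwhere(~block)
                pick = rng.permutation(len(free))[: target - painted]
                block[tuple(free[pick].T)] = True
            fiber[i * f:(i + 1) * f, j * f:(j + 1) * f] = block

    img = np.empty((h * f, w * f, 3), dtype=np.float64)
    img[...] = BACKGROUND_RGB
    img[fiber] = FIBER_RGB
    if color_jitter > 0:
        img += rng.integers(-color_jitter, color_jitter + 1, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return SlideImage(img, pixel_size_um=voxel_size_mm * 1000.0 / f)


def _line_pixels(r0, c0, r1, c1, f):
    from skimage.draw import line

    rr, cc = line(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
    keep = (rr >= 0) & (rr < f) & (cc >= 0) & (cc < f)
    return rr[keep], cc[keep]


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class PhantomDataset:
    """Everything the pipeline consumes, with ground truth attached.

    ``signals`` keys: spgr_low, spgr_high, bssfp_low, bssfp_high, mt_off,
    mt_on, dam_1, dam_2.
    """

    spec: PhantomSpec
    labels: LabelVolume
    truth: ParameterMaps
    depth: np.ndarray
    b1: B1Map
    signals: dict[str, SignalVolume]
    slide: SlideImage
    slide_plane_index: int
    lesion_specs: list[LesionSpec]


def generate_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Generate the complete synthetic dataset for one specimen.

    Pipeline: geometry -> depth field -> tissue parameters -> lesions ->
    B1 field -> forward simulation of the eight acquisitions -> Rician noise
    -> synthetic stained slide of the central coronal plane. Bit-reproducible
    given the spec (all randomness is derived from ``spec.seed``).
    """
    from .cortex import depth_field

    labels = build_geometry(spec)
    depth = depth_field(labels)
    maps = assign_tissue_parameters(labels, spec, depth=depth)

    lesions = spec.lesion_specs
    if lesions is None:
        lesions = auto_lesions(labels, depth)
    lesioned_spec = dataclasses.replace(spec, lesion_specs=lesions)
    labels, maps = implant_lesions(labels, maps, lesioned_spec, depth)

    b1 = generate_b1_field(spec)

    defect_mask = None
    if spec.banding_defect is not None:
        idx = np.indices(labels.data.shape).astype(np.float64)
        c = spec.banding_defect.center
        dist = np.sqrt(sum((idx[i] - c[i]) ** 2 for i in range(3))) * spec.voxel_size
        defect_mask = dist <= spec.banding_defect.radius_mm
    factors = spec.banding_defect.factors if spec.banding_defect else (1.0, 1.0)

    clean = {
        "spgr_low": simulate_spgr(maps, SPGR_LOW, b1),
        "spgr_high": simulate_spgr(maps, SPGR_HIGH, b1),
        "bssfp_low": simulate_bssfp(maps, BSSFP_LOW, b1, defect_mask, factors[0]),
        "bssfp_high": simulate_bssfp(maps, BSSFP_HIGH, b1, defect_mask, factors[1]),
    }
    clean["mt_off"], clean["mt_on"] = simulate_mt_pair(maps, b1)
    dam_scale = spec.tissue_table["cortex"].m0
    clean["dam_1"], clean["dam_2"] = simulate_dam_pair(b1, 20.0, scale=dam_scale)

    signals = {
        name: add_rician_noise(vol, spec.noise_sigma, seed=spec.seed * 97 + k)
        for k, (name, vol) in enumerate(clean.items())
    }

    plane = labels.data.shape[1] // 2
    slide = render_histology_slide(
        maps.myelin[:, plane, :],
        upsample_factor=spec.upsample_factor,
        seed=spec.seed,
        voxel_size_mm=spec.voxel_size,
    )

    return PhantomDataset(
        spec=lesioned_spec,
        labels=labels,
        truth=maps,
        depth=depth,
        b1=b1,
        signals=signals,
        slide=slide,
        slide_plane_index=plane,
        lesion_specs=list(lesions),
    )
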