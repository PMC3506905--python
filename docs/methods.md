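# Methods

This note documents the models, the synthetic specimen, the numerical
choices, and their limitations. Nothing stated here goes beyond what the
test suite and `scripts/acceptance.py` compute.

## Signal models and inversion

All acquisitions are magnitude steady-state volumes on a common 0.35 mm
isotropic grid (0-based voxel indices, axis order (x, y, z), world =
index × voxel size; coronal planes are constant-y).

* **SPGR** (spoiled gradient echo): S = M0 sin(α_e)(1 − E1)/(1 − cos(α_e)E1),
  E1 = exp(−TR/T1), α_e = ΔB1·α. Protocol: TR 7.7 ms, TE 3.35 ms, flips
  4° and 22° (angles suited to the short T1 range of fixed tissue).
* **bSSFP** (balanced steady-state free precession), on-resonance ideal:
  S = M0 sin(α_e)(1 − E1)/(1 − E1E2 − (E1 − E2)cos(α_e)), E2 = exp(−TR/T2).
  Protocol: TR 7.7 ms, TE 3.84 ms, flips 20° and 70°. Echo-time decay and
  off-resonance phase are not modeled; banding is represented only as an
  injectable multiplicative defect, mirroring an exclusion-based (not
  correction-based) treatment of artifacts.
* **Magnetization transfer**: a proton-density-weighted SPGR pair (25°,
  TR 25 ms, TE 4.09 ms) without and with saturation, the saturated signal
  multiplied by (1 − δ). δ is the tissue saturation fraction, so
  MTR = (S0 − Ssat)/S0 × 100 = 100 δ identically. MTR is semi-quantitative;
  no two-pool Bloch–McConnell model is attempted.
* **Transmit field**: double-angle pair S1 ∝ cos(ΔB1 α), S2 ∝ cos(2ΔB1 α),
  α = 20°, sharing an arbitrary spatial proportionality factor.

Inversions are exact two-point closed forms (the protocol acquires exactly
two angles per method, so least squares over more angles would be vacuous):
DESPOT1 linearization slope → T1 and M0; DESPOT2 slope plus the fitted T1 →
T2; quadratic 2c² − rc − 1 = 0 → ΔB1 (root c ∈ (0,1); r ≥ 1 has no
solution and is flagged). **Validity policy:** any voxel whose closed form
leaves the physical branch (DESPOT1 slope ∉ (0,1), E2 ∉ (0,1), S0 ≤ 0) is
flagged invalid and excluded downstream — never clamped, because clamping
would bias group statistics. In the noiseless limit the full chain
(simulate → add B1 inhomogeneity → fit with B1 correction) is exact to
floating-point precision; the suite asserts 1e-6 relative.

**B1 grid.** By default the transmit map is computed on the signal grid.
A coarse-acquisition mode (`AnalysisConfig.b1_coarse_factor`) down-samples
the double-angle pair and trilinearly upsamples the fitted map, emulating a
low-resolution B1 acquisition; it is not the default because interpolation
breaks the exact noiseless round trip the suite verifies.

**Banding exclusion.** A two-point fit has zero residual by construction,
so corrupted bSSFP voxels cannot be detected from their own fit. Instead the
bSSFP line's intercept implies an independent proton density,
M0_bssfp = b(1 − E1E2)/(1 − E1), which is compared with the
spoiled-acquisition M0; relative disagreement above `banding_tol`
(default 0.2, chosen to sit far above the few-percent disagreement produced
by measurement noise at the default SNR while catching order-unity banding
defects) excludes the voxel from all statistics. Injected defect regions
recorded in the signal metadata are always excluded, which makes the
bookkeeping exactly testable.

## The synthetic specimen

The phantom emulates a formalin-fixed hemisphere: a white-matter core with a
small central "subcortical grey" sphere, wrapped by a cortical ribbon 6–10
voxels thick, immersed in formalin. Folding is a low-order sinusoidal radial
perturbation of the WM surface (reproducible gyri and sulci with a
well-defined pial boundary, not anatomical realism). Default grid 128³.

**Tissue table** (fixed post-mortem values; mean (SD)):

| class | T1 ms | T2 ms | M0 r.u. | MTR % | myelin % area |
|---|---|---|---|---|---|
| normal-appearing cortex | 209 (27) | 64 (11) | 3797 (114) | 7.47 (1.26) | 7.96 (6.69) |
| cortical lesion | 236 (26) | 91 (22) | 3835 (86) | 7.09 (1.09) | 1.96 (2.55) |
| normal-appearing WM | 196 (18) | 56 (13) | 3467 (88) | 12.82 (0.90) | 74.18 (4.70) |
| WM lesion | 380 (88) | 121 (27) | 4005 (111) | 6.16 (2.79) | 27.55 (14.32) |
| formalin | 2200 (50) | 800 (30) | 5000 (100) | 0.5 (0.2) | 0 |

The formalin row is a package choice of plausible fixed-formalin values
(long relaxation times, essentially no macromolecular pool); no published
row exists for it. Subcortical grey reuses the cortical row.

**Myelin distributions.** Myelin SDs are of the same order as their means,
so zero-truncated Gaussians would bias means by several tenths of a point.
All myelin draws therefore use gamma distributions matched to the row's
first two moments (positive support, right-skewed, exact mean/SD).
Relaxation/M0/δ draws in non-cortical tissue use truncated Gaussians
(truncation is ≥ 6 SD away and negligible); T2 is capped at 0.95 T1
voxel-wise to keep the bSSFP model valid (affects < 1 % of WM-lesion draws).

**Laminar cortex.** Fractional cortical depth d ∈ [0,1] is computed from
two Euclidean distance transforms, d = Dp/(Dp + Dw) (Dp to formalin, Dw to
WM-like tissue), replacing a deformable-surface extraction with a voxel
method adequate at this scale — laminar results are therefore qualitative
with respect to surface-based analyses. Cortical lesions stay part of the
ribbon for depth purposes, and subcortical grey counts as WM. Cortical
myelin mixes a monotone depth profile (default linear; sigmoid available)
with voxel noise at `laminar_contrast` 0.7, then rank-maps the scores onto
the gamma quantile ladder of the NAC row — the cortex-wide marginal matches
the row's mean/SD by construction while myelin rises with depth.

**Rate-linear couplings.** Within the ribbon the remaining parameters are
deterministic functions of myelin m: 1/T1 = a1 + κ1 m, 1/T2 = a2 + κ2 m,
δ = a3 + κ3 m, M0 = a4 − κ4 m, with (a, κ) solved so m = 1.96 reproduces
the lesion row and m = 7.96 the NAC row exactly. All κ must be positive
(monotone demyelination physics); a table violating this is rejected. Two
consequences are intentional: the time-vs-content relation is convex
(relaxation times rise steeply as m → 0), and the *cortex-wide mean* of a
coupled parameter exceeds the row value slightly (Jensen; ≈ +3 ms for T1 at
the default myelin spread) — the anchor rows are recovered exactly only at
the anchor myelin values, which is what the noiseless suite asserts.
M0 declining with myelin reproduces the observed negative M0–myelin
correlation alongside higher M0 in lesions.

**Lesions.** Subpial (type III) lesions relabel cortical voxels within a
tangential radius (default 6 mm) of a pial seed whose fractional depth is
below `depth_fraction` (default 0.5); their myelin is redrawn from the
lesion row and re-coupled, so lesions remain on the cortical
myelin–parameter relation (demyelination, not separate physics). Focal WM
lesions are spheres (default 2.5 mm radius, shrunk to fit small cores)
drawn independently from their row — WM lesions break the cortical
monotone relation, as the tissue table itself shows. Default placement is
automatic at geometrically valid sites (two subpial, one WM focal).

**Transmit field and noise.** ΔB1 is a random quadratic polynomial over the
grid scaled to exactly [1 − amplitude, 1 + amplitude] (default ±20 %).
Measurement noise is Rician, S' = √((S + n1)² + n2²), with one effective σ
(default 5 r.u., ≈ SNR 50 on the low-flip SPGR over cortex) summarizing the
heavy signal averaging of a long post-mortem protocol; no per-average
simulation. No published noise level exists for the emulated acquisition,
so σ is chosen to make the tissue-table SDs attainable without claiming to
match any scanner. All randomness derives from child streams of a single
seed; datasets and reports are bit-reproducible.

**Histology rendering.** Each MR-resolution block of the slide (default
upsample factor 10, i.e. 35 µm pixels — a desk-scale stand-in for true
micron-scale scanning) is painted with randomly oriented fiber strokes in
the chromogen color until the painted-pixel count equals
round(content/100 × factor²) exactly, over the counterstain background,
plus bounded per-pixel color jitter that preserves the red−blue sign. The
rendered content is therefore recoverable to one block pixel (1 % at
factor 10) by construction — this quantization, not segmentation error, is
the accuracy floor of the histology chain, which is why end-to-end myelin
checks use ±1–2 points where the MR parameters use 1e-6.

## Statistics

* Student's pooled-variance two-sample t-test (two-sided, α 0.05) by
  default, matching the emulated analysis; Welch is available because the
  table variances differ severely between groups. Two zero-variance groups
  with equal means give p = 1 by convention.
* Bonferroni factor 5 (T1, T2, M0, MTR, myelin); the correction family size
  is a package choice.
* Pearson and tie-aware (average-rank) Spearman correlations, computed on
  the eroded cortical ribbon of the histology plane against the recovered
  myelin content map. Zero variance yields an undefined flag, not an error.
* Histograms: 64 uniform bins over the pooled 1st–99th percentile range,
  with explicit under/overflow bins so the normalized mass is exactly 1.
* Cortical ROI statistics use the 6-connectivity-eroded cortical mask (one
  pass removes exactly the face-boundary partial-volume layer) and respect
  both validity masks and the banding exclusion; excluded-voxel counts are
  reported in the audit.

## What the phantom does and does not establish

Passing tests show that the estimation chain is exact in the noiseless
limit, robust at the modeled SNR, and that the statistical machinery
recovers the contrasts and correlation signs implied by the generating
tissue model. They do not validate the tissue model against any real
specimen: real cortical folding, fixation gradients, reception-field bias,
off-resonance physics, stain variability, slice distortion and nonlinear
histology-to-MR registration are all absent by design (the phantom renders
histology in register; registration is exercised only with known affine
perturbations). Published empirical correlation magnitudes from single
specimens are data-dependent and are not reproduction targets; only signs
and qualitative structure are.

One property is scale-sensitive and worth flagging: rank correlation
dominance (|ρ| ≥ |r|) for T1 against myelin holds at the 64³ test specimen
and in the low-noise limit, but at the full 128³ default — where the fixed
6 mm lesions cover only ~2 % of the cortex, thinning the near-zero-myelin
tail that drives the nonlinearity — fitted-T1 rank degradation from noise
outweighs the mild curvature and |ρ| falls ~0.1–0.4 % short of |r|. T2,
whose rate coupling is far more curved, shows |ρ| > |r| robustly at every
scale. The corresponding acceptance-level test is left failing rather than
retuned, and this paragraph is its analysis.

## Default problem sizes

Unit and property tests run on 20³ oracles and a 64³ specimen; the full
default pipeline (128³, ≈ 2.1 M voxels, slide rendering included) is run
once in the suite and completes in well under a minute on one CPU core.
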