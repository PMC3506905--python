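# cortiq

Quantitative MRI characterization of cortical demyelination, end to end, on a
synthetic fixed-hemisphere specimen with known ground truth.

Cortical lesions in multiple sclerosis — especially type III subpial lesions,
which demyelinate the superficial cortical laminae and spread tangentially
along the pial surface — are notoriously hard to see on MRI: their myelin
contrast against normal-appearing cortex (NAC) is small compared to the
natural variation in cortical myeloarchitecture. `cortiq` is for researchers
who want a fully controlled test bed for this problem: it forward-simulates a
high-resolution (0.35 mm isotropic) post-mortem quantitative MRI protocol on a
digital phantom, inverts the acquisitions back into parameter maps, quantifies
myelin from synthetic immunostained slides, and reproduces the voxel-wise
statistical comparison of lesional versus normal cortex — with every step
testable against the generating truth.

## The model

**Forward signal models.** Spoiled gradient echo (SPGR) and on-resonance
balanced SSFP steady-state magnitudes,

    S_SPGR  = M0 sin(α_e) (1 − E1) / (1 − cos(α_e) E1)
    S_bSSFP = M0 sin(α_e) (1 − E1) / (1 − E1 E2 − (E1 − E2) cos(α_e))

with E1 = exp(−TR/T1), E2 = exp(−TR/T2) and effective flip α_e = ΔB1·α.
Magnetization transfer is a multiplicative attenuation (1 − δ) of a
proton-density-weighted SPGR, so MTR = (S0 − Ssat)/S0 × 100 = 100 δ. The
transmit field enters through a double-angle pair, S1 ∝ cos(ΔB1 α),
S2 ∝ cos(2 ΔB1 α).

**Inversion.** Two-point closed forms matching the two-angle protocol:
the variable-flip-angle (DESPOT1) linearization Y = E1 X + M0(1 − E1) with
Y = S/sin α, X = S/tan α gives T1 = −TR/ln(slope); the analogous bSSFP
linearization (DESPOT2) gives E2 = (E1 − m)/(1 − m E1); the double-angle
ratio r = S2/S1 solves 2c² − rc − 1 = 0 for c = cos(ΔB1 α). Unphysical
voxels are flagged invalid, never clamped.

**Tissue model.** Each tissue class (NAC, cortical lesion, normal-appearing
WM, WM lesion, formalin) carries mean/SD values of T1, T2, M0, MTR and myelin
content (% area) for fixed post-mortem tissue. Inside the cortex, myelin
follows a pial→WM laminar gradient and the other parameters are coupled to
myelin *linearly in rate* (1/T = a + κ·m), two-point calibrated on the
lesion and NAC rows — producing the strongly non-linear relaxation-time vs
myelin-content relation seen in fixed cortex.

**Histology.** Slides are rendered as red-brown chromogen fiber strokes on a
light-blue counterstain; segmentation thresholds the normalized red-blue
contrast (R − B)/(R + B) and block-averages the binary map to MR resolution,
giving a 2D myelin content map in % of local area.

**Statistics.** Per-tissue mean/SD tables over eroded cortical masks
(6-connectivity, one partial-volume layer), two-sided two-sample t-tests with
5-fold Bonferroni correction, Pearson r and Spearman ρ against myelin
content, voxel-count-normalized histograms, and laminar profiles sampled
from a distance-transform fractional depth field.

## Worked example

```python
from cortiq import PhantomSpec, run_pipeline

spec = PhantomSpec(grid_shape=(64, 64, 64), cortical_thickness_vox=7,
                   wm_radius_frac=0.30, fold_amplitude_vox=2.0, seed=11)
results = run_pipeline(spec)
print(results.summary())
```

prints

```
cortiq 0.1.0 — cortical quantitative MRI analysis

Per-tissue summaries (mean, SD, n):
  parameter                    NAC                CL              NAWM         WM_lesion
  t1 [ms]          210.13 ( 20.73)   236.72 ( 14.71)   196.32 ( 19.76)   377.56 ( 93.76)
  t2 [ms]           67.00 ( 15.38)    93.41 ( 13.18)    56.01 ( 13.30)   120.05 ( 27.04)
  m0 [r.u.]       3797.22 ( 92.12)  3834.48 ( 90.34)  3467.98 (122.54)  4001.08 (145.14)
  mtr [%]            7.48 (  0.82)     7.09 (  0.81)    12.81 (  1.18)     6.11 (  2.89)
  myelin [% area]     8.96 (  5.33)     1.94 (  3.08)    74.23 (  4.73)               —

Group comparisons (two-sided t, Bonferroni-corrected):
  CL_vs_NAC          t1      t =     80.79  p_corr = 0 *
  CL_vs_NAC          t2      t =    106.55  p_corr = 0 *
  CL_vs_NAC          m0      t =     24.74  p_corr = 2.99e-133 *
  CL_vs_NAC          mtr     t =    -29.04  p_corr = 1.85e-182 *
  CL_vs_NAC          myelin  t =    -15.77  p_corr = 9.82e-48 *
  ...
Correlations with myelin content (histology plane):
  t1      r = -0.921  rho = -0.930  (n = 729)
  t2      r = -0.924  rho = -0.984  (n = 729)
  m0      r = -0.385  rho = -0.369  (n = 729)
  mtr     r = +0.439  rho = +0.407  (n = 729)
```

Reading this: the fitted tissue means recover the generating values (e.g.
lesional T2 93 ms vs normal cortex 67 ms — demyelinated cortex has longer
relaxation times, higher proton density, lower MTR); every lesion contrast
survives Bonferroni correction; relaxation times correlate negatively with
myelin content and the rank correlation exceeds the linear one where the
rate coupling bends hardest (T2). The same analysis is available from the
shell (`cortiq run --out DIR --seed 11`), which additionally writes the
fitted NIfTI maps, the myelin content TIFF, CSV tables, `report.json` and a
provenance manifest; `cortiq generate` writes the raw synthetic dataset and
`cortiq fitmaps` / `cortiq myelin` run the inversion and histology stages on
existing files.

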