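# Methods

## Problem and model

Radiotherapy delivered through scalp transducer arrays (tumor-treating
fields, TTFields) raises the superficial dose under the electrodes. This
package quantifies the resulting skin-toxicity risk and the mitigation
obtained by varying the array positions, using four ingredients:

1. **Scalp shells.** The skin is represented by two 2 mm layers below
   the body surface (0–2 mm and 2–4 mm). Depth is a physical Euclidean
   distance, so the construction is valid on anisotropic dose grids.
2. **DVH reduction.** Each shell's cumulative dose–volume histogram is
   reduced to hot-spot doses per area (D<sub>0.05 cm²</sub>,
   D<sub>25 cm²</sub>; area × thickness = volume) and to the generalized
   equivalent uniform dose
   gEUD = (Σᵢ (vᵢ/V_ref) Dᵢ^{1/n})ⁿ, the power mean over partial volumes
   taken relative to a reference organ of 100 cm² of skin (× 2 mm =
   20 cm³).
3. **Lyman–Kutcher–Burman NTCP.** NTCP = Φ((gEUD − TD50)/(m·TD50)) with
   the Burman fit of the Emami skin-necrosis tolerances: TD50 = 70 Gy,
   m = 0.12, n = 0.10. The equivalent Kutcher–Burman route (effective
   volume v_eff at maximum dose with TD50(v) = TD50·v⁻ⁿ) is implemented
   separately and agrees to < 10⁻⁶ in probability by construction
   (gEUD = D_max·v_eff ⁿ); the package tests both routes against each
   other. Physical accumulated dose enters the model; an optional EQD2
   transform (user-supplied α/β) is available but off by default, which
   is the convention that makes the normo- and hypofractionated arms
   directly comparable in the tables this package reproduces.
4. **Positioning scenarios.** Five electrode conditions: (1) no
   electrodes, (2) positions varying per fixation period as observed,
   (3) fixed at the sampled placement nearest the average position,
   (4) 2/5 of fractions as (1) + 3/5 as (3), (5) 2/5 as (1) + 3/5 as
   (2). Mixes are deterministic convex combinations of accumulated
   courses — identical to fraction-by-fraction bookkeeping when the
   per-fraction plans are equal, and exactly reproducible. Accumulated
   courses are renormalized by N = prescription / (imaged fractions ×
   dose per fraction), using each course's own prescription.

The statistical layer fits ln NTCP = μ + patient + scenario + ε on the
complete patient × scenario design (NTCPs are log-normal-like; the raw
values fail a Lilliefors-corrected KS normality check while the logs
pass). The multiplicative effect of scenario a vs b is
exp(effect_a − effect_b), which on a balanced design equals the
geometric mean of the per-patient NTCP ratios; its 95% CI uses the
residual mean square with (P−1)(S−1) degrees of freedom. The natural
logarithm is used throughout (the base cancels in factors). NTCP values
are floored at 10⁻¹² (with a warning) before logging to guard against
underflow in synthetic cohorts with very deep targets.

## Sub-voxel surface depth

Scalp shells demand depth accuracy well below one voxel: at 1–2 mm grid
resolution a distance transform to outside-voxel centers misplaces the
0–2 mm shell boundary by up to a voxel (on a 50 mm analytic sphere at
1 mm voxels the superficial shell volume errs by −13%, and no threshold
on the lattice-quantized distances fixes it). The package instead
anti-aliases the mask with an isotropic physical Gaussian of scale σ and
inverts the planar step response: smoothing a half-space gives occupancy
φ = Φ(d/σ) at signed depth d, hence d = σ·Φ⁻¹(φ). σ defaults to twice
the coarsest voxel spacing (≥ 2 mm) and is raised to half the deepest
requested shell depth; the estimate is accurate to ≲ 0.15 mm within
~2σ of the surface and monotone beyond, with a curvature bias of order
σ²/R (≈ 0.1 mm on an 80 mm head). Internal air cavities are filled
before the depth is computed; erosion by 0 mm is defined as the body
itself so that boundary voxels with slightly negative depth estimates
stay in the outermost shell and the identity
shell(0,2] ∪ shell(2,4] = body ∖ erosion(4 mm) holds exactly.

## DVH conventions

Cumulative DVHs use exact at-or-above counting on bin edges from 0 Gy in
steps of 0.05 Gy by default (below the rounding of any reported metric);
dose-at-volume inverts the curve with linear interpolation, and
differential bins use bin-center doses (second-order accurate for the
power mean). Partial volumes outside the structure contribute zero dose,
so structures smaller than the reference organ are implicitly padded
with unirradiated skin. All internal math is double precision; rounding
happens only at the presentation layer.

## Synthetic data

No deposited image/dose data exist for this analysis, so the
`synthetic` module generates the full study geometry:

- **Phantom.** Spherical head (default radius 80 mm) on a 1.5 mm grid
  (matching a clinical dose-calculation grid), spherical PTV
  parameterized by radius and depth below the scalp. Planned dose is
  prescription-level inside the PTV times a plan hot-spot factor,
  decays exponentially (length 40 mm) with distance outside it, and is
  reduced toward the surface by a buildup deficit of 0.28 recovering
  with 2.5 mm e-folding depth. These four numbers were calibrated once
  so that a cohort of PTV radii 30–52 mm at depths 0–14 mm spans
  superficial-shell gEUDs of roughly 31–48 Gy, NTCPs from ~10⁻⁶ to
  ~10⁻², and gEUD depth gradients of 2.8–3.7 Gy/mm — the ranges a
  seven-patient glioblastoma cohort exhibits.
- **Arrays.** Four 3×3 arrays (anterior/posterior/left/right) of 20 mm
  disk electrodes at 30 mm pitch, projected onto the scalp. Placement
  varies per fixation period on each array's tangent plane with
  principal-axis SDs of 1.1 cm and 0.7 cm (the corresponding 95%
  confidence-ellipse half-axes are ≈ 2.7 / 1.7 cm). The fixed-position
  scenario snaps to the sampled placement minimizing the summed squared
  distance to the per-array mean offsets.
- **Electrode dose effect.** Parametric, not transport-based: dose is
  multiplied by 1 + g·max(0, 1 − depth/4 mm) with g = 0.12 under an
  electrode footprint and g = 0.03 in the array halo. The default gives
  a superficial-shell dose increase of ~7–8% under an array, consistent
  with the reported sub-8.5% buildup outside the hottest cm², vanishes
  by 4 mm depth, and is strictly weaker in the 2–4 mm layer than in the
  0–2 mm layer.
- **Outcome-level emulator.** `simulate_log_ntcp_table` draws balanced
  tables directly from the additive log-NTCP model (patient SD 2.5,
  residual SD 0.37, baseline median 0.111%, scenario factors 1 / 3.53 /
  5.49 / 2.29 / 1.95). It exists for parameter-recovery checks, where
  the true scenario factor must be known exactly — through the voxel
  pipeline the realized factor depends on the sampled geometry. Patient
  effects are truncated at ±1.5 SD so probabilities stay far from 1;
  clipping values instead would bias the hottest patients' contrasts.

**What passing tests do and do not show.** The generator reproduces the
orderings, signs and magnitudes of the analysis (electrode scenarios
raise hot-spot dose and NTCP; fixed > varying > part-time mixes; gEUD
grows with depth; large superficial targets dominate risk). It does not
emulate real anatomy (non-spherical heads, ears/nose, bolus effects),
beam-direction-specific buildup, inter-fraction anatomy change, or the
electrode physics (high-Z attenuation/backscatter); patient-specific
hot-spot values such as the printed D-metrics therefore cannot be and
are not reproduced from phantoms — only their qualitative structure is.

## Numerical choices and problem sizes

- gEUD factors out D_max before raising to 1/n = 10 for stability.
- Degenerate inputs: empty masks, zero reference volume, non-positive
  bin widths, incongruent grids (shape/spacing/origin named in the
  error), constant vectors in rank correlation, < 5 samples in the
  normality test, and configs without a seed all raise immediately.
- Scenario weights must sum to 1 (tolerance 10⁻⁹); fraction weights
  must be non-negative.
- The test suite runs cohorts at reduced size (head radius 55–70 mm,
  2 mm voxels, 7 patients, 8 fixation periods — about 6 s per cohort)
  and shares one cohort across the ordering and statistics checks;
  the CI-coverage check uses 400 closed-form simulated tables. These
  sizes are the package's own choice of a fast, converged regime; the
  defaults (80 mm head, 1.5 mm grid, 10 fixation periods) remain the
  study-scale configuration.

## Known limitations

- Single static geometry per patient; no deformable registration.
- Masks only — no polygon/DICOM-RT structure sets.
- The Lyman skin model is applied to 2 mm layers; estimates at the
  0.07 mm basal-layer depth would be lower, so absolute NTCPs are
  conservative (over-)estimates, more so without electrodes.
- No electric-field modelling, no skin-recovery kinetics between array
  fixations, and no beam-transport physics; the electrode gain model is
  a calibrated stand-in for the dosimetric footprint of the arrays.
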