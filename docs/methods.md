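# Methods

This note documents the models implemented in `microstim`, the defaults and
why they were chosen, the numerical conventions, and the limitations of the
synthetic data the test suite runs on.

## Dispensing–diffusion model

A hollow micropipette probe held at height *h* above the dish dispenses
agonist solution (reservoir concentration *C₀*) at volumetric rate *Q*.
Away from the immediate vicinity of the aperture, advection is negligible
and the agonist spreads by molecular diffusion; the dish surface acts as a
reflecting plane. We model the field as a continuous point source of
strength *Q·C₀* with an image source (factor 2), evaluated on the plane:

    C_ss(r)  = Q·C₀ / (2π·D·r_eff),      r_eff = max(√(r² + h²), a)
    C(r, t)  = C_ss(r) · erfc( r_eff / (2√(D·t)) )           for t ≤ t_disp
    C(r, t)  = C(r, t) − C(r, t − t_disp)                    for t > t_disp

with *r* the in-plane distance from the point beneath the aperture, *a* the
aperture radius (1 μm, half the 2 μm opening) flooring the singularity, and
the post-dispense branch the exact linear superposition of a switched-on
and a delayed switched-off source.

**Parameters.**

| parameter | default | rationale |
|---|---|---|
| D | 5×10⁻¹⁰ m²/s | Stokes–Einstein scale for a ~314 Da small molecule (R848) in aqueous medium at 37 °C |
| h | 4 μm (single-cell), 20 μm (cluster) | probe retraction distances of the two dispensing modes |
| Q | ≈0.23 pL/s (single-cell), ≈20 pL/s (cluster) | calibrated so C_max = 100 nM at the reference conditions C₀ = 5.5 μM / h = 4 μm and C₀ = 0.318 μM / h = 20 μm; absolute flow rates are not independently known, so the (C₀, C_max) anchors define them |
| a | 1 μm | aperture radius; r_eff floor |

The calibration constants are recomputed from the anchors using the
configured diffusivity, so changing *D* preserves the C_max anchors.
Because the anchor ties *Q·C₀/h* to 100 nM, C_max is exact at the anchors
and the *shape* of the field (1/r_eff decay, erfc build-up) is the model
content. The test suite verifies the closed form against an independent
finite-volume radial diffusion solver (steady state by direct linear solve
on a 40 mm domain; transients by explicit stepping) to within 2–5%, and
checks flux conservation (the diffusive flux through any hemisphere around
the source equals *Q·C₀* to 1%).

The single-cell C_max carries ~50% uncertainty from cell height: the
aperture-to-cell-surface distance may be up to twice the nominal 4 μm, and
since C_max ∝ 1/h the deviation from the nominal value reaches 50%.
`relative_cmax_uncertainty` reports exactly this: the largest deviation over
a height interval relative to the nominal C_max.

**Not modeled:** advection/jetting at the aperture, media convection,
3-D structure above the dish (adherent cells sample the surface plane).

## Synthetic cultures and the response model

**Spatial layout.** Cultured RAW 264.7 macrophages grow in clumps, so
positions are drawn from a Thomas cluster process: parent centres from a
homogeneous Poisson process at rate `density/8` per mm² (a mean of 8 cells
per clump), offspring counts Poisson(8), offspring positions Gaussian with
σ = 12 μm, clipped to the field. Density presets: sparse 400 cells/mm²,
dense 3750 cells/mm² (the plating densities used for density comparisons);
the sparse/moderate/dense classification thresholds are <1000 and
≥2500 cells/mm².

**Reporter ratios.** Resting nuclear/cytoplasmic NF-κB ratios are
log-normal with median 0.75 and log-sd 0.2; activated ratios log-normal
with median 1.5 and log-sd 0.2. These place resting cells below 1 and
activated cells above it with modest overlap — the correct ordering and a
realistic dynamic range, though the exact distributions in any given
microscope setup will differ (real calibration data should be substituted
via `fit_cutoff` when available).

**Response model.** The probability that a cell activates is logistic in
log₁₀ concentration with a density- and time-dependent threshold:

    p(C) = b + (1−b)·σ( k·(log₁₀C − log₁₀EC50_eff) )
    EC50_eff = EC50 · (1 + β·max(0, ρ/ρ_ref − 1)·h(t))
    h(t) = max(0, (t_restore − t)/(t_restore − t_min))

and p = b for stimulation shorter than t_min. Defaults: EC50 = 100 nM
(the minimally activating concentration), k = 4, b = 0.05, ρ_ref = 1000
cells/mm², t_min = 5 min (shortest stimulus that elicits any response),
t_restore = 15 min (stimulation time at which dense cultures respond like
sparse ones), and β = 36/11 so that a 3750 cells/mm² culture at a 5-minute
stimulus has exactly a tenfold-elevated threshold. The functional form is
deliberately phenomenological: it encodes the observed density suppression
and its relaxation with stimulation time, choosing a *threshold* shift
(rather than a slope or maximum-response change, which the data do not
distinguish). It asserts no mechanism.

**Compounding of background and calling.** Ground-truth activation is
Bernoulli(p); activated cells draw activated-distribution ratios.  Because
the calibration cutoff leaves 5% of resting cells above it by
construction, the *called* fraction in a null experiment is
b·P(activated ratio > cutoff) + (1−b)·0.05 ≈ 9.6%, not b alone.  Tests and
downstream expectations account for this compounding; when comparing
groups the compounding largely cancels.

**What the generator does not emulate:** cell motility and division,
secreted-factor reaction–diffusion (only its net effect on the threshold),
time-resolved translocation trajectories, segmentation artifacts of real
microscopy, plate-to-plate calibration drift. Passing tests therefore
validate the analysis machinery and the qualitative density/time logic,
not the biological parameter values.

## Imaging

Rendering paints each cell as a cytoplasm disk (radius 9 μm) at its
cytoplasmic intensity with the nuclear disk (radius 5 μm) overwritten at
nuclear intensity, so the painted N/C ratio equals the record's ratio by
construction; Poisson shot noise is applied (photon scale 1/noise_level).
Quantification: Otsu threshold on the nuclear channel, connected
components, nucleus-area filter 25–400 μm², then mean reporter intensity
inside each nucleus and in a 3 μm outward expansion ring (`expand_labels`
splits contested territory by proximity, so neighboring nuclei are never
sampled). Mean rather than median intensities; pixel size 0.65 μm/px
(10× objective class); all constants configurable. This is a minimal,
transparent stand-in for a full image-cytometry pipeline; round-trip tests
require exact cell-count recovery for non-overlapping fields and <5%
median ratio error at default noise.

## Activation calling and uncertainty

The cutoff is the empirical 95th percentile (numpy linear interpolation
between order statistics — the convention is fixed and documented because
different quantile rules move the cutoff by O(1/n)) of a resting sample of
at least 20 cells; calls use strict inequality, so ties at the cutoff are
conservatively not called. Separate calibrations per experimental setup
are supported and serialized with a sample hash. Fraction activated
carries a bootstrap SE (resampling cells with replacement, SD of resampled
fractions, percentile 95% CI); for binary calls this converges to the
binomial √(p(1−p)/n), which the tests verify to 10%.

## Resampling inference

- **Exceedance test:** pools the two groups' calls, draws target-sized
  samples *with replacement*, counts resamples whose fraction reaches the
  observed target fraction (inclusive ≥), and reports the add-one p-value
  (e+1)/(B+1). With-replacement resampling makes the resampled count exactly
  Binomial(n_target, pool fraction), which the tests exploit as a
  closed-form oracle.
- **Permutation ANOVA:** statistic is the size-weighted between-group sum
  of squares of group means — monotone-equivalent to F under label
  permutation, without needing a within-group variance estimate. When the
  number of distinct label assignments is ≤ 20 000 the null is enumerated
  exactly (p = e/total); otherwise random permutations with the add-one
  p-value. Calibration is verified: null rejection at α = 0.05 over 2000
  replicate datasets stays within [3.5%, 6.5%].
- **Rank-sum:** two-sided Wilcoxon/Mann-Whitney; exact enumeration when
  both groups have ≤ 8 values (tie-aware via mid-ranks), otherwise the
  normal approximation with tie and continuity corrections.
- **Effect sizes:** difference in fraction activated (percentage points)
  and percent change in median N/C ratio, both with ±1 bootstrap-SD
  uncertainties from independent within-group resampling.

All resampling is deterministic given a seed; add-one p-values never reach
zero.

## Dose–response fitting

Fraction activated vs concentration is fitted by maximum binomial
likelihood to the same logistic-in-log-dose form as the response model,
with the background *fixed* at the calibration false-positive rate (0.05):
with ≤ 6–7 doses per panel a free background trades off against EC50 and
is poorly identified. Deterministic multi-start (7 log-spaced EC50 starting
values spanning the dosed range × slope starts 1 and 4, L-BFGS-B on
(log₁₀EC50, log k)) avoids local optima; all-zero or all-one panels are
refused as unidentifiable. `threshold_crossing` inverts the fitted curve
analytically; levels outside (background, 1) are refused.

## Ligand budget

Free ligand in a sample box (default 45×45×5 μm ≈ 10.1 pL) is C·V·N_A;
bound ligand is n_cells × receptors_per_cell × C/(C+K_d). Defaults
receptors_per_cell = 5000 and K_d = 100 nM are order-of-magnitude
assumptions (they must be stated with any reported run); the conclusion —
tens to hundreds of free ligands per bound one even for a 9-cell cluster —
is robust to an order of magnitude in either.

## Pipeline and reproducibility

A virtual experiment runs: culture generation → field or bath stimulus →
response simulation → (optional render + quantify, with image-derived
ratios replacing generator ratios for matched cells) → calibration on a
resting companion sample (n = 1000) → calling → neighbor counts →
bootstrap fraction + spatial summaries. Stage failures abort with a
stage-tagged error. All stage seeds derive from the single config seed via
`numpy.random.SeedSequence`; identical config + seed reproduces output
files byte-for-byte. Every CSV carries a provenance header (package
version, seed, config hash).

## Problem sizes used in tests

The suite exercises: 1 mm² fields at 200–3750 cells/mm²; 200-replicate
count calibration; 100-seed EC50 recovery at 200 cells/dose; 2000-replicate
(unit) and 500-replicate (acceptance) permutation-ANOVA calibration at
n_perm = 399; finite-difference grids of 2 μm (40 mm domain for steady
state, 1.5 mm for transients); 150–200-cell rendered images at 0.65 μm/px.
These sizes give stable statistics for every tolerance asserted while the
full suite completes in well under a minute.

## Known limitations

- The diffusion model's absolute flow rates are calibration constants, not
  measurements; only the anchored (C₀, C_max) pairs and the field shape
  are meaningful.
- The response model is phenomenological; recovering its parameters from
  synthetic data says nothing about the mechanism of density-dependent
  suppression.
- The center-region definition (cells above a steady-concentration
  threshold) is one reasonable operationalization of "the stimulated
  area"; others (fixed radius) are supported via `SpatialParams`.
- No edge-corrected spatial statistics; neighbor counts at field borders
  are biased low, as in the original counting procedure.
- No multiple-testing correction across condition panels; p-values are
  per-comparison.
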