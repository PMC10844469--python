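# microstim

Analysis pipeline for **localized TLR-agonist stimulation of macrophage
cultures**: when a micropipette probe dispenses picoliter volumes of the
TLR7/8 agonist R848 over a single RAW 264.7 macrophage — or a cluster, or
the whole dish — which cells translocate NF-κB into the nucleus, and how
does the answer depend on agonist concentration, stimulation time, and how
densely the cells are plated?

The package is aimed at quantitative cell biologists who want to analyze
(or simulate, for power analysis and method validation) such experiments.
It provides, as composable library modules plus a `microstim` CLI:

- **`diffusion`** — the concentration field under continuous dispensing
  from an aperture at height *h* over the dish: a continuous point source
  of strength *Q·C₀* against a reflecting plane,
  *C(r) = Q·C₀ / (2πD·r_eff)* with erfc build-up and superposition decay,
  where *r_eff = max(√(r²+h²), a)*.
- **`synthetic`** — Thomas-cluster-process cultures (macrophages grow in
  clumps) with log-normal nuclear/cytoplasmic (N/C) reporter ratios, and a
  logistic dose–response model whose threshold shifts up with culture
  density and relaxes with stimulation time.
- **`imaging`** — rendering of two-channel (nuclear stain + reporter)
  images from cell records and Otsu-segmentation-based N/C ratio
  quantification.
- **`calling`** — calibration-cutoff activation calling: the cutoff is the
  95th percentile of a resting population's N/C ratios; fraction activated
  carries bootstrap uncertainty. Plus serial dilution-wash arithmetic.
- **`spatial`** — neighbor counts within 18 μm, sparse/moderate/dense
  classification, 100 μm square binning, radial activation profiles, and
  center-region (concentration-thresholded) fractions.
- **`resampling`** — the inference layer: pooled with-replacement
  exceedance test, permutation ANOVA (between-group sum of squares, exact
  enumeration on small instances), tie-aware Wilcoxon rank-sum, bootstrap
  effect sizes for fractions and medians.
- **`dose`** — binomial maximum-likelihood logistic fits of fraction
  activated vs log₁₀ dose, with analytic threshold inversion.
- **`budget`** — free vs receptor-bound ligand counts in a ~10 pL sample
  box, to test whether ligand uptake can explain density effects.
- **`pipeline` / `config` / `cli`** — YAML-configured end-to-end virtual
  experiments and replicate panels.

## Worked example

```python
import numpy as np
import microstim as ms

# cluster-mode dispensing: reservoir 0.318 uM, probe 20 um above the dish
cond = ms.DispenseConditions(c0_nM=318.0, mode="cluster", duration_s=300.0)
print(round(cond.cmax_nM, 1))                                  # 100.0
print(round(ms.steady_state_concentration(150.0, cond), 1))    # 13.2

# one virtual cluster-stimulation experiment at moderate plating density
cfg = ms.PipelineConfig(
    mode="cluster",
    culture=ms.CultureConfig(density=2000.0, seed=1),
    dispense=cond,
    t_stim_min=5.0,
    seed=1,
)
exp = ms.run_virtual_experiment(cfg)
r = exp.result
print(f"{r.n_activated}/{r.n_cells} activated "
      f"({r.fraction_activated:.3f} +/- {r.bootstrap_se:.3f})")
# 235/2114 activated (0.111 +/- 0.007)
cf = ms.center_fraction(exp.cells, exp.field, 30.0, seed=0)
print(f"center (>=30 nM): {cf.n_activated}/{cf.n_cells}")      # 1/15

# two-group comparison: 17/20 targeted cells vs 120/2000 bath-stimulated
target    = np.r_[np.ones(17), np.zeros(3)].astype(bool)
reference = np.r_[np.ones(120), np.zeros(1880)].astype(bool)
eff = ms.effect_size_difference(target, reference, seed=13)
exc = ms.exceedance_test(target, reference, seed=13)
print(f"difference {eff.value:.1f} +/- {eff.se:.1f} pp; "
      f"exceedances {exc.exceedance_count}/5000, p = {exc.p_value:.5f}")
# difference 79.0 +/- 8.0 pp; exceedances 0/5000, p = 0.00020
```

The peak surface concentration (`C_max`) is 100 nM for the calibrated
cluster conditions; 150 μm out the steady gradient has fallen to 13 nM.
In the virtual experiment only 11% of the moderately dense culture is
called activated, and in the high-concentration center only 1 of 15 cells —
density suppresses the short-stimulus response (rerunning with
`t_stim_min=15` lifts the center to 3/15). The two-group comparison shows
an activation difference of 79 ± 8 percentage points, and none of 5000
pooled resamples reach the targeted group's fraction.

The CLI mirrors the library:

```sh
microstim simulate --density 400 --seed 1 --out cells.csv
microstim run --config experiment.yaml --out results/
microstim budget --concentration 100
```

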