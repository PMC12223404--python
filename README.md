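# memriq

Quantification pipeline for **manganese-enhanced cardiac MRI (MEMRI)** of
acute myocardial ischemia–reperfusion injury, validated end-to-end on a
digital left-ventricle phantom with known ground truth.

Mn²⁺ enters viable cardiomyocytes through calcium channels, shortens T1 and
brightens perfused myocardium on T1-weighted imaging. During a coronary
occlusion the downstream territory receives no tracer, so a dynamic series
acquired across occlusion and early reperfusion separates perfused from
ischemic tissue. This package implements the analysis chain such a study
needs, for preclinical imaging scientists who want each step testable
against a phantom rather than against hand contours:

- **VFA T1 mapping** — per-voxel T1/M0 from multi-flip-angle spoiled
  gradient-echo volumes via the standard linearization of
  S(α) = M0·sin α·(1−E1)/(1−E1·cos α), E1 = exp(−TR/T1), with an optional
  Gauss–Newton refinement and a log-polynomial multiplicative bias-field
  correction.
- **Slope-criterion perfusion deficit** — per-pixel signal-intensity slope
  over the occlusion window, ΔSI/Δt by default (end-of-ischemia minus
  baseline over elapsed time, per-voxel OLS as an option); the deficit is
  the percentage of LV myocardium with a **nonpositive** slope (%LV).
- **Threshold enhancement fractions** — remote septal ROI mean ± k·SD
  (k = 2 default): hyper-enhancement above the threshold for LGE area at
  risk, hypo-enhancement below mean − k·SD for the MEMRI deficit at the end
  of ischemia.
- **Volumetrics and wall mechanics** — EDV/ESV/EF by slice summation over
  cine masks, segmental wall thickness by radial ray casting, fractional
  wall thickening fWT = 100·(WT_ES − WT_ED)/WT_ED.
- **Cohort statistics** — Welch's t-test, Spearman correlation with exact
  permutation p at small n, and simple regression with a CI on the
  intercept (the between-modality "offset").
- **Phantom** — a short-axis annulus (matrix 120×110×10, FOV 28×25×8 mm³)
  with saturating mono-exponential Mn²⁺ wash-in in perfused tissue, linear
  non-increase in a lateral ischemic sector, an 11-frame/66-min dynamic
  window split at 30 min, SPGR stacks at FAs [2,5,8,11,14]°/TR 11.1 ms,
  LGE-like volumes, 20-frame cine, bias fields, Gaussian or Rician noise —
  all with exact truth manifests.

## Worked example

```python
from memriq.phantom import PhantomSpec, simulate_memri_dynamics, sector_width_for_fraction
from memriq.perfusion import split_windows, pixel_slope_map, deficit_from_slopes

spec = PhantomSpec(ischemic_sector_deg=sector_width_for_fraction(30.0),
                   noise_sigma=2.5, seed=3)   # SNR 40 vs the s0=100 baseline
series, truth = simulate_memri_dynamics(spec)
labels = truth.extras["labels"]
ischemia, reperfusion = split_windows(series, t_occlusion=30.0)
smap = pixel_slope_map(ischemia, labels, mode="endpoint")
res = deficit_from_slopes(smap, labels)
print(f"deficit {res.deficit_pct_lv:.2f} %LV vs truth {truth.deficit_fraction_true:.2f} %LV")
```

prints

```
deficit 30.12 %LV vs truth 30.83 %LV
```

i.e. at SNR 40 the nonpositive-slope criterion recovers the designed 30.8
%LV ischemic sector to within ~0.7 percentage points; noise-free it is
exact to the voxel quantum.

The same workflow is scripted in `analysis/01…06`, which generate a
16-subject synthetic cohort (7 IRI / 6 sham / 3 naive), validate each
estimator against the phantom truth, and run the group comparisons; each
script prints its findings and writes a CSV under `results/`. The CLI
(`memriq phantom|t1map|memri|enhance|function|stats|cohort`) exposes the
same stages on NIfTI inputs.

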