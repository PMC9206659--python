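# pshg — widefield polarimetric SHG tissue analysis

`pshg` implements an analysis pipeline for **widefield polarimetric
second-harmonic-generation (P-SHG) microscopy** of fibrillar collagen, the
kind of data used to probe extracellular-matrix remodeling in tumors.  A
sample is imaged under 16 combinations of incident (PSG) and analyzed (PSA)
polarization states — left circular, horizontal linear, right circular and
vertical linear on each side — and the pipeline turns those 16 co-registered
intensity images into quantitative ultrastructural maps, texture features
and a tissue classification:

1. **Reduced Stokes reconstruction.**  Per PSG state *p*, the four analyzed
   intensities give the outgoing SHG Stokes elements
   `s0 = (I_H + I_V + I_R + I_L)/2`, `s1 = I_H − I_V`, `s3 = I_R − I_L`
   (s2 is not measured).  The redundancy `(I_H+I_V) − (I_R+I_L)` is reported
   as a consistency residual.
2. **Polarimetric parameter maps.**  Five per-pixel parameters:
   - `ICP = (s0_RCP + s0_LCP)/2` — orientation-independent SHG intensity;
   - `R = χ⁽²⁾zzz/χ⁽²⁾zxx` from `A = (s0_RCP+s0_LCP)/(s3_RCP−s3_LCP)` via
     `R = 1 + 2A ± 2√(A²−1)` (both quadratic roots implemented; the branch
     is calibrated against the built-in forward model);
   - `DCP = (|s3_RCP|/s0_RCP + |s3_LCP|/s0_LCP)/2` — degree of circular
     polarization;
   - `SHG-CD = 2(s0_RCP − s0_LCP)/(s0_RCP + s0_LCP)` ∈ [−2, 2];
   - `SHG-LD = 2(s0_VLP − s0_HLP)/(s0_VLP + s0_HLP)` ∈ [−2, 2].
   Background pixels (SNR below a z-score threshold, default 3) and pixels
   with no real R root become NaN under a shared validity mask.
3. **Masked texture features.**  Each map is tiled into sub-images
   (64 per core by default); per tile and parameter the mean, mean absolute
   deviation (MAD) and five Haralick features — contrast, correlation,
   entropy, angular second moment, inverse difference moment — are computed
   from a direction-averaged grey-level co-occurrence matrix that *skips
   NaN pixels*, plus the SHG pixel density, giving 36 features per tile.
4. **Group statistics.**  Per-group 1st–99th percentile trimming,
   Kruskal–Wallis omnibus tests and Dunn–Bonferroni post hoc pairwise
   comparisons (p < 0.05 significant, p < 0.001 highly significant);
   features with no significant normal-vs-tumor difference are excluded
   from classification.
5. **Classification.**  Binary logistic regression under repeated
   stratified five-fold cross-validation (out-of-fold probabilities pooled
   per repeat, 50 % posterior threshold) with a 12-metric panel reported as
   mean ± SD across repeats, canonical feature-subset comparisons, held-out
   core prediction and a sub-image subdivision sweep.

Because real tissue microarray data of this kind is not publicly deposited,
the package ships a **physics-based synthetic generator**
(`pshg.synthetic`): collagen-like curvilinear fiber fields with known
per-pixel susceptibility ratio, 3-D orientation, chirality and amplitude
are pushed through a cylindrically symmetric (Kleinman-restricted) χ⁽²⁾
forward model to exact outgoing Stokes vectors, analyzed into the 16-state
stack and corrupted with detector noise.  Every stage of the pipeline is
validated against this ground truth.

## Worked example

```python
import json
from pshg.config import RunConfig, SimulateOptions, ClassifyOptions
from pshg.pipeline import run_pipeline

cfg = RunConfig(
    out_dir="demo", seed=1,
    simulate=SimulateOptions(n_cores_per_group=4, core_size=256),
    classify=ClassifyOptions(repeats=20, held_out_cores=["normal_00", "tumor_00"]),
)
out = run_pipeline(cfg)
metrics = json.loads((out / "metrics.json").read_text())
```

This simulates 8 tissue cores (4 normal, 4 tumor) with the default group
presets, reconstructs parameter maps, extracts features, tests group
differences and trains the classifier.  On this run it prints:

```
predictors: 31 rows: 319
accuracy: 0.997 +/- 0.000
f1: 0.996 +/- 0.000
auroc: 1.000 +/- 0.000
brier: 0.003 +/- 0.000
held-out accuracy: 1.0
subset accuracies: {'all_params_pd': 0.963, 'complete': 0.997,
                    'intensity_pd': 0.941, 'intensity_pd_texture': 1.0}
excluded: ['icp_contrast', 'dcp_entropy', 'dcp_asm', 'shg_cd_mean', 'shg_ld_mean']
```

Reading: of the 36 features, 5 showed no significant normal-vs-tumor
difference and were excluded (note that the SHG-CD and SHG-LD *means* drop
out — fibers are randomly oriented in both groups, only their spread
differs); the remaining 31 predictors separate the groups essentially
perfectly, intensity + pixel density alone does measurably worse than the
complete feature set, and the two held-out cores are classified correctly
tile by tile.

The same pipeline is available from the shell:

```bash
pshg run-all --seed 1 --out demo
pshg sweep-subdivision --seed 1 --out demo --levels 1,2,4,8
```

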