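# endowm

Analysis toolkit linking **peripheral endothelial function** to **white-matter
health** in aging cohorts. It implements, as a tested and reusable library,
the bespoke computations of that analysis chain:

- **WMH volumetrics** (`endowm.wmh`) — white-matter hyperintensity volume from
  a FLAIR-like intensity volume and WM mask. The WM intensity histogram is fit
  with a two-Gaussian mixture by weighted nonlinear least squares; lesions are
  voxels above `mu + k*sigma` of the dominant (normal-appearing WM) component,
  with k = 2.33 by default. Volumes are reported in mm³ and as % of
  intracranial volume (ICV), globally and within a frontal submask, plus a
  tail-corrected "excess volume" estimate.
- **Reactive hyperemia index** (`endowm.pat`) — RHI from a fingertip
  pulse-amplitude (PAT) recording with baseline / cuff-occlusion /
  post-occlusion phases: the ratio of post- to pre-occlusion mean per-beat
  pulse amplitude (peak-to-trough).
- **Connectivity-based hard segmentation** (`endowm.connseg`) — each seed
  white-matter voxel is assigned to the cortical target with the strictly
  largest streamline count; per-target voxel tallies are normalized by target
  mask size (`100 * voxels / mask_voxels`) and compared across subjects with a
  repeated-measures ANOVA and Bonferroni-corrected pairwise tests.
- **Voxelwise FA inference** (`endowm.voxelwise`) — skeleton-space regression
  `FA ~ RHI + age + sex` per voxel, with family-wise error controlled by a
  Freedman–Lane max-statistic permutation test, and extraction of the
  significant cluster's per-subject mean FA.
- **Cohort statistics** (`endowm.cohort`) — Trail Making Test switching cost
  (Trail B − Trail A), upper-tail 2.5-SD outlier exclusion, residual-based
  partial correlations controlling for age and sex, two-group sex F-tests,
  and demographics-table summaries.
- **Synthetic data with planted truth** (`endowm.synthetic`) — FLAIR-like
  ellipsoid phantoms with a two-component WM intensity mixture and spherical
  lesions, three-phase PAT signals with a known amplitude ratio, seed-to-target
  count tables with a known winning target per voxel, latent-Gaussian-copula
  cohort tables, and skeleton-space FA matrices with a planted RHI effect.
  Every downstream stage is tested against this planted truth; no external
  data are required.

## Worked example

Run the end-to-end synthetic pipeline (defaults: 72³ phantom with two planted
lesions, 60/30/30-s PAT recording with true ratio 1.73, 6 subjects × 7
connectivity targets, n = 36 cohort, 400-voxel FA skeleton with a planted
40-voxel RHI effect, 500 permutations):

```bash
endowm run --out runs/demo            # or: endowm run --config configs/demo.yaml --out runs/demo
```

Equivalently in Python:

```python
from endowm import run_pipeline
summary = run_pipeline(None, out_dir="runs/demo")
```

Selected numbers this run prints (deterministic for the default seed 7):

| quantity | value | meaning |
|---|---|---|
| fitted dominant mode | mu = 100.01, sigma = 9.99 | matches the generating N(100, 10) WM intensity law |
| WMH threshold | 123.27 | mu + 2.33 sigma of the dominant fit |
| global WMH | 2354 mm³ (1.43 % of ICV) | raw supra-threshold volume, lesions + expected Gaussian tail |
| excess WMH volume | 1455 mm³ | tail-corrected estimate; planted truth is 1440 mm³ |
| RHI | 1.7235 | true simulated post/pre amplitude ratio is 1.73 |
| target ANOVA | F(6, 30) = 70.8, p = 2.3e-16 | normalized target percentages differ across the 7 targets |
| voxelwise cluster | 13 of 360 skeleton voxels, max &#124;t&#124; = 7.3 | overlaps the planted 40-voxel RHI-effect block |
| partial r (FA, Trail B − Trail A) | r = −0.449, p = 0.008, df = 32 | controlling age and sex; the cohort generator plants negative latent correlations |
| partial r (RHI, Trail B − Trail A) | r = −0.383, p = 0.025, df = 32 | idem |

Per-stage JSON reports (`wmh.json`, `rhi.json`, `connseg.json`,
`voxelwise.json`, `stats.json`, `summary.json`) land in the run directory;
every report embeds the exact config and its hash, and a rerun with the same
config is bit-identical.

Single-stage CLIs are available too, e.g.

```bash
endowm simulate pat --seed 2 --out sim/
endowm rhi --signal sim/pat.csv --out rhi.json
```

## Acceptance script

`scripts/acceptance.py` re-runs the complete pipeline from scratch at a given
seed — generating all synthetic inputs, then executing WMH quantification,
RHI computation, connectivity segmentation, voxelwise permutation inference
and the cohort statistics — and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The per-stage reports are written next to it under `results/acceptance_run/`.

See `docs/methods.md` for the statistical model behind each stage, parameter
defaults and units, numerical choices, and known limitations.
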