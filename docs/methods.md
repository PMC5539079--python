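# Methods

This note documents the models and procedures implemented in `endowm`, the
assumptions behind them, the parameters that matter, the numerical choices,
and what the synthetic-data tests do and do not establish.

## 1. WMH volumetrics (`endowm.wmh`)

**Model.** Within a white-matter mask, FLAIR-like voxel intensities are
treated as a two-component Gaussian mixture
`w1·N(mu1, sigma1) + w2·N(mu2, sigma2)`, `w1 + w2 = 1`: a dominant
normal-appearing-WM mode plus a secondary (partial-volume or lesion)
population. The mixture is fit to the binned intensity *density* (default
256 bins spanning the masked intensity range) by weighted nonlinear least
squares with Poisson bin errors `sqrt(max(count,1)) / (N·binwidth)`.
Hyperintensities are voxels **strictly above** `mu_dom + k·sigma_dom`
(`k = 2.33`), where the dominant component is the one with the larger mixing
weight (exact ties go to the lower mean, since normal WM is hypointense
relative to lesions on FLAIR). Volumes are voxel counts times the voxel
volume from the NIfTI header zooms, reported absolutely and as % of ICV.

**Fit initialization and restarts.** Deterministic starts: a weighted 1-D
2-means split of the histogram mass, a single-Gaussian "collapse" start
(which guarantees the mixture never fits worse than the best single
Gaussian), an upper-tail start seeding component 2 on the top 2 % of
intensity mass (without it, small lesion loads are invisible to the mass
split), plus five jittered restarts from a fixed-seed generator. The whole
procedure is deterministic.

**Guarding against an unidentifiable second component.** On a unimodal
histogram, two heavily overlapping components split the mode arbitrarily and
the "dominant" sigma — hence the threshold — becomes noise. The second
component is therefore kept only if (a) its weight is at least 0.01 and its
sigma at least one bin width, (b) the components are separated by Ashman's
`D = |mu2−mu1|·sqrt(2/(sigma1²+sigma2²)) > 2` (the conventional bimodality
bar), and (c) the weighted SSE improves on the single-Gaussian fit by more
than the 0.999 quantile of chi²(3) (the mixture's three extra parameters
must earn their keep; the likelihood-ratio null for mixtures is heavier than
chi², hence the combination with (b)). Otherwise a single Gaussian is
refitted and returned flagged `degenerate=True` with `w = (1, 0)`.

**Expected tail and the excess-volume estimate.** A Gaussian tail of mass
`1 − Phi(k)` (≈ 0.99 % at k = 2.33) always exceeds the threshold, so the raw
supra-threshold volume overestimates true lesion load by about
`w_dom · N_wm · (1 − Phi(k))` voxels — at a 2 % lesion load that is a ~50 %
relative overshoot. `excess_lesion_volume` subtracts this model-expected
tail (clipped at zero) and is the quantity that recovers planted lesion
volume; the raw volume remains the primary, protocol-faithful output.

**Not implemented by design:** bias-field correction, skull stripping,
registration, anatomical WM segmentation (inputs arrive pre-masked), and
connected-component or minimum-size lesion filters.

## 2. Reactive hyperemia index (`endowm.pat`)

RHI is the ratio of post- to pre-occlusion average pulse amplitude. Beats
are local maxima separated by at least half the estimated beat period
(median spacing of a permissive first-pass peak search, prominence 25 % of
the interval's range); a beat's amplitude is its peak minus the following
trough — the conventional plethysmographic peak-to-trough pulse amplitude
(an RMS-envelope variant, `sqrt(8)·SD`, is available). `pre_avg` averages
the whole baseline phase; `post_avg` the whole post phase or an optional
`(start_s, end_s)` window. The occlusion phase is a quality check only:
`occlusion_ok` is False when the occlusion residual amplitude reaches 10 %
of baseline, but the ratio is still returned (the commercial device's
proprietary normalizations are unpublished; this is the plain stated ratio,
not a device-equivalent value).

The index is scale-invariant and, in the noise-free limit,
duration-invariant. The synthetic generator uses desk-scale phase durations
(60/30/30 s versus the clinical 10/5/5 min), a 1.25 Hz beat with 80 samples
per beat (so noise-free beats are sampled identically and the recovered
ratio is exact to machine precision), and 1 % amplitude noise by default.

## 3. Connectivity hard segmentation (`endowm.connseg`)

Each seed voxel is assigned to the target with the strictly largest
streamline count, provided it reaches `min_count` (default 1); exact ties
and all-zero voxels are `UNASSIGNED` (a `tie_break="first"` switch exists
for tools that award ties in target order). Per-target voxel counts are
normalized as `100 · voxels / target_mask_voxels` to control for cortical
region size. Across subjects, target percentages are compared with a
repeated-measures one-way ANOVA (subjects as blocks,
`df = (T−1, (T−1)(n−1))`; with 7 targets and 6 subjects that is (6, 30)),
followed — only when the omnibus p < alpha — by paired t-tests with
Bonferroni correction `min(1, p·n_pairs)`. A between-subjects error model
(`df = (T−1, T(n−1))`) is available because the appropriate error term for
such percentages is analysis-dependent; the reported df always make the
choice explicit.

## 4. Voxelwise FA inference (`endowm.voxelwise`)

The skeleton is `mean FA > 0.2` (strict). At each skeleton voxel the model
is OLS `FA ~ intercept + RHI + age + sex`; the t statistic of the RHI
coefficient is computed via Frisch–Waugh residualization (predictor and FA
both residualized on the nuisance block), which is numerically identical to
the full OLS t. Constant-FA voxels yield t = 0; perfect fits are flagged
±inf; rank-deficient designs raise an error naming the collinear columns.

**Permutation FWE.** Freedman–Lane style: the residualized predictor is
permuted and *re-residualized* on the nuisance space before correlating
(without the second residualization the permuted predictor's norm is
overstated and the test is measurably anti-conservative). The corrected
p-value of a voxel is the proportion of permutations — identity included in
Monte-Carlo mode, `p = (1+b)/(1+B)` — whose maximum |t| over the skeleton
reaches the observed |t|; when `n! ≤ n_perm` all `n!` permutations are
enumerated and the p-value is exact. Exceedances are counted with a 1e-10
relative epsilon so exact ties (the identity permutation above all) survive
BLAS rounding. Two-sided by default; a one-sided directional mode exists.
Max-statistic correction is used instead of cluster-enhancement methods
(TFCE): it controls FWE exactly but defines significance voxel-by-voxel, so
cluster extents are not comparable with TFCE-based analyses. Significant
voxels (corrected p < 0.05) form the "cluster", whose per-subject mean FA
feeds the cohort correlations; an empty cluster is a valid result.

## 5. Cohort statistics (`endowm.cohort`)

Executive cost is `Trail B − Trail A` seconds. Outlier exclusion is a
single pass over all non-missing scores: exclude strictly above
`mean + 2.5·SD` (sample SD), upper tail only; the rule is deliberately not
iterated. Note that in small samples a single extreme value inflates the SD
enough to retain itself — e.g. in {30, 32, 34, 36, 200} the cutoff is 253.2
and nothing is excluded; the rule only bites when the bulk of the sample
pins down the SD. Associations are residual partial correlations: x and y
are each regressed on `[1, age, sex]`, the residuals correlated,
`df = n − 2 − k`, two-sided p from the t transform. Sex differences are
one-way two-group ANOVA F with df `(1, n−2)`, identical to the squared
pooled-variance t. Sex is coded 0/1 (F/M) in all design matrices.

## 6. Synthetic data (`endowm.synthetic`)

What the generators emulate — and what they do not:

- **Phantom**: nested ellipsoids (brain ⊃ WM) with the WM mixture and
  spherical lesions in voxel index space; ICV is the brain-ellipsoid voxel
  count times voxel volume; the "frontal" submask is a coronal half-space
  cut at `frontal_plane`. No anatomy, bias fields, noise correlations or
  partial-volume geometry: only the intensity statistics that drive
  histogram-based lesion quantification are realistic. Defaults (dominant
  N(100, 10), secondary N(140, 15), lesion N(160, 8) ≈ mu+6·sigma) put the
  lesion population well clear of the 2.33-sigma threshold.
- **PAT**: sinusoidal carrier with a piecewise-constant phase envelope and
  additive white noise; no dicrotic notch, drift, or heart-rate
  variability. The true post/pre ratio is the envelope ratio by
  construction.
- **Connectivity**: per-voxel counts with the planted winner's mean highest
  (Poisson, or negative-binomial when `dispersion > 1`); noise-free mode
  makes the winner deterministic so hard segmentation must recover the
  truth exactly.
- **Cohort**: a latent standard trivariate Gaussian over (RHI, cluster FA,
  TMT cost) with configurable correlation, mapped linearly to the stated
  marginals (defaults: n = 36; age 63.8 (2.9) y; RHI 1.73 (0.5); Trail B −
  Trail A 35.4 (15.5) s; FA 0.50 (0.06), a field-typical corpus-callosum
  value). TMT-A is drawn independently (30 (8) s) and TMT-B = TMT-A + cost.
  Age and sex are independent of the latent triplet. Positive-valued
  variables are clipped away from zero (astronomically rare at the
  defaults). Default latent correlations (+0.40 RHI–FA, −0.36 RHI–cost,
  −0.45 FA–cost) reproduce the sign structure of the associations the
  analysis battery is meant to detect.
- **FA skeleton dataset**: per-voxel baseline FA N(0.5, 0.08) shared across
  subjects, subject noise N(0, 0.04), a fraction of deliberately
  sub-threshold voxels to exercise skeleton masking, and a contiguous
  planted block carrying a linear RHI effect (FA units per RHI unit).

A green test on these generators establishes that the estimators recover
known truth under the assumed statistical model — not that they are robust
to registration error, scanner artifacts, non-Gaussian intensity tails, or
physiological confounding in real data.

## 7. Determinism and reproducibility

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical spec + seed gives bit-identical
output. The pipeline derives per-stage seeds from the run seed by fixed
offsets, embeds the full config and its SHA-256 hash in every report, and
writes no timestamps, so a rerun with the same config is byte-identical.

## 8. Known limitations

- The WMH fit assumes at most two well-separated intensity populations;
  multi-modal pathology (e.g. mixed lesion intensities) collapses into the
  secondary component.
- The excess-volume correction assumes the dominant component is truly
  Gaussian; heavy-tailed real FLAIR intensities would bias it.
- Beat detection assumes a quasi-periodic pulse; arrhythmic signals may
  drop beats (an error is raised below two detected beats).
- The repeated-measures ANOVA uses the sphericity-assuming F; no
  Greenhouse–Geisser correction is applied (percentages across targets are
  compared descriptively in the intended use).
- Permutation inference assumes exchangeable subjects under the null
  (no family or repeated-measures structure).
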