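# Methods

## The statistic

Network homogeneity (NH) measures how coherently a voxel fluctuates with the
rest of a network: for voxel *v* in mask *M* (m voxels), NH(v) is the mean
Pearson correlation between *v*'s time series and each other in-mask series.
`nh_values` computes this with standardized-series matrix products in
O(m·T); the literal O(m²) pairwise loop is kept (`compute_nh_pairwise`) as an
independent oracle and the two are held to 1e-10 agreement in the tests. For
an m-voxel region whose voxels share a latent signal with pairwise correlation
ρ, the population NH of every region voxel equals ρ — the identity that ties
the synthetic generator's ground truth to the measured maps.

## Synthetic cohort

The generator emulates the study design the pipeline targets: three groups
(defaults 31 melancholic / 28 nonmelancholic / 32 control), TR 2.5 s, 200
volumes, an isotropic 3 mm grid of 24×28×22 voxels with an MNI-style centered
affine. Six box-shaped network regions (48–60 voxels, within the 22–83-voxel
range of typical reported cluster extents) carry one latent time course each;
voxel series are √ρ·latent + √(1−ρ)·noise, so within-region coupling — and
hence regional NH — is ρ exactly in population. Group effects are planted
through per-group ρ (right PCC/precuneus and right angular up in both patient
groups, right MTG down in both, left ITG down and bilateral SMFG up
specifically in the melancholic group, nonmelancholic SMFG below controls).
Per-subject heterogeneity is a Gaussian jitter on ρ (SD 0.08, clipped to
[0.02, 0.93]). The coupling deltas were chosen analytically, once, so that the
pairwise group t-statistics clear the voxel p < 0.001 threshold at n≈30 after
the ~(region size / mask size) dilution that whole-network NH imposes, while
leaving single cluster features short of perfect separability (LOOCV accuracy
in the 70–90% range rather than 100%).

Motion traces are slow random walks (0.02 mm translation steps, ~100× smaller
rotation steps) plus optional transient spikes; defaults keep every subject
under the 2 mm / 2° exclusion rule so the default cohort retains all 91
subjects, and `forced_exclusions` plants guaranteed super-threshold spikes for
tests of the exclusion path. Clinical scores are Gaussian with the configured
per-group means/SDs; controls carry no TEPS scores (missing values). The
designated scores (defaults: TEPS total and TEPS contextual anticipatory) are
coupled to the designated region's (right MTG) realized NH by an exact
in-sample calibration: the score is a linear function of the standardized
realized NH vector plus sample-orthogonalized Gaussian noise, so the sample
correlation equals the target (−0.5) and the sample mean/SD equal the
configured values exactly. The realized NH used for the coupling is measured
the way the analysis measures it — whole-network NH after discard, detrend,
band-pass and nuisance regression, averaged within the region — so the planted
correlation survives to the extraction stage instead of being attenuated by
preprocessing. Uncoupled scores are plain Gaussian draws; their sample moments
(not their population) may drift from the configured values, and low-mean
scales can produce small negative values, which no downstream stage requires
to be nonnegative.

What the generator does **not** emulate: hemodynamic autocorrelation,
physiological noise spectra, scanner drift, motion-correlated signal
artifacts, spatial normalization error, or inter-region functional coupling.
Passing tests therefore demonstrate that the pipeline recovers what it is
pointed at under a clean, well-specified signal model — not that it is robust
to every artifact of real data.

## Preprocessing

Order: discard (default 10 volumes) → motion exclusion → linear detrend →
band-pass → nuisance regression. Exclusion compares displacement from the
first retained frame per axis, strict `>` at 2 mm / 2°. FD follows the Power
convention (sum of absolute frame-to-frame parameter changes, rotations as arc
length on a 50 mm sphere; first frame 0), computed after the discard. The
band-pass is an ideal zero-phase FFT filter retaining 0.01–0.08 Hz inclusive
and removing DC; it is exactly idempotent, which lets nuisance regressors be
filtered identically before regression so residuals cannot re-acquire
out-of-band frequencies. Nuisance regressors: WM mean, CSF mean, Friston-24
expansion (6 parameters, lag-1 copies, both squared) and an intercept; the
global mean is deliberately not removed. Rank-deficient designs are pruned
greedily with a warning.

## DMN mask

Group spatial ICA: per-subject temporal PCA (1.5×C components), group PCA of
the concatenated reduced data to C components (default 20; the synthetic
pipeline uses 8 since only six latent sources exist), seeded FastICA
(tolerance 1e-6, max 500 iterations), maps z-scored with positive-skewness
sign fixing, subject maps by dual regression. Components are selected by
absolute spatial correlation with a template (threshold 0.3, argmax fallback
with a warning); the mask is the union over groups and selected components of
group-mean subject-map voxels above z = 1. "Union" was chosen over
"intersection" to keep every candidate network voxel available for NH testing;
mask construction is monotone in the threshold.

## Group inference

A cell-means GLM with mean-centered covariates (age, education, mean FD) is
fit per in-mask voxel: omnibus three-group F by model comparison against the
covariates-only model, pairwise contrasts as t maps over the whole mask (not
restricted to F-significant voxels, since the pairwise cluster table is the
primary readout). Smoothness is estimated from variance-normalized GLM
residuals by inverting a Gaussian autocorrelation at lag 1
(FWHM = √(−2 ln 2 / ln ρ₁) voxels, ρ₁ = 1 − var(Δ)/2), floored at one voxel so
the resel count never exceeds the voxel count; on simulated fields this
recovers a 6 mm kernel within a few percent and returns exactly one voxel for
white noise. Cluster correction uses the standard 3D Gaussian-random-field
expected-cluster-count and extent formulas (t/F thresholds are mapped to the
Gaussian scale through the probit of the voxel p-value; extent tail
probability exponential in k^(2/3)); clusters form under 26-connectivity
(configurable), and signed maps are processed one tail at a time so cluster
tables carry signed peak statistics. On 500 simulated smooth null fields
(6 mm FWHM) the family-wise cluster error rate sits near the nominal 0.05 —
the acceptance suite recomputes this. On unsmoothed fields the GRF
approximations are anti-conservative; the smoothness floor mitigates but does
not remove this, which is the standard caveat for random-field inference on
rough maps. NH maps are intrinsically smooth inside equicorrelated regions, so
residual smoothness estimates on the synthetic cohort run high (~10 mm); that
makes the cluster test conservative there, which the strong planted effects
absorb.

## Clinical statistics

One-way ANOVA and LSD post hocs are reconstructed algebraically from per-group
mean/SD/n (identical to raw-data ANOVA, which the tests verify), two-sample
tests are pooled-variance t (the pooled form reproduces the reference table's
illness-duration statistic; Welch does not), gender tables use Pearson χ²
without continuity correction, correlations are two-tailed Pearson on
pairwise-complete observations, and multiplicity is handled by
Benjamini–Hochberg step-up (order-preserving; cross-checked against a literal
evaluation of the definition and against statsmodels). The BH family for an
NH–score correlation is the set of abnormal clusters the score is tested
against — with a 9-cluster family this maps raw p 0.005 → 0.045 and
0.004 → 0.036, the reference worked examples.

## Classification

LOOCV SVM (RBF kernel, C = 1, γ = 1/n_features; configurable, linear kernel
available), feature standardization fit on each training fold only to avoid
leakage, melancholic as the positive class. Every nonempty feature subset up
to a size cap (default 2, mirroring the reported single-and-pairwise search)
is scored; ties break toward fewer features, then lexicographic names.
Reported metrics are accuracy, sensitivity and specificity at two-decimal
percentage precision.

## Orchestration and reproducibility

`run_pipeline` executes the stages in order on in-memory arrays (preprocessed
runs are held as float32, ~1 GB for the default cohort), drops
motion-excluded subjects from everything downstream, and writes a summary
(JSON + Markdown), cluster TSVs and the subject table. One global seed fans
out to the simulate/ICA/classification stages through fixed
`SeedSequence(seed, spawn_key=(stage,))` derivations; a completed output
directory whose stored config hash and seed match is left untouched.

## Problem sizes used in validation

The validation studies run at: 500 null-field replicates on the full
24×28×22 grid for the GRF error rate (20 residual fields per replicate for
smoothness estimation); one full default-cohort run (91 subjects) for
sign-pattern recovery; 20 seeded replicates with the melancholic group at
full size (n = 31) for the correlation-recovery rate, measured through the
temporal pipeline on the network voxels (the compact rearrangement is exact
because every preprocessing stage is voxelwise in time); and a 59-patient
planted-signal cohort for the feature-pair recovery.

## Known limitations

- The GRF extent formulas assume smooth stationary Gaussian fields; severe
  anti-conservatism on unsmoothed data is documented behavior, not a bug.
- Group ICA here is plain temporal-concatenation ICA with dual regression;
  no ICASSO stability analysis, and no attempt to reproduce any particular
  toolbox's numerical output.
- The generator's regions are disjoint boxes with a single latent each;
  spatial autocorrelation within regions is total and between regions zero,
  both more extreme than real data.
- Smoothing within the mask renormalizes at edges, so post-smoothing NH can
  leave [−1, 1] slightly; values are intentionally not clipped.
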