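# nhkit

Network-homogeneity (NH) analysis of the resting-state default-mode network
(DMN), built for studies that compare melancholic major depressive disorder
(MDD), nonmelancholic MDD, and healthy controls. The package covers the whole
analysis chain — and ships a synthetic-cohort generator with known ground
truth, so every stage is testable without any imaging data download.

## What it computes

For a voxel *v* inside a network mask *M* with |M| = m voxels, the network
homogeneity is the mean Pearson correlation between its time series and every
other in-mask series:

    NH(v) = (1 / (m - 1)) * sum_{u in M, u != v} r(x_v, x_u)

The pipeline around this statistic:

1. **Synthetic cohort** — three groups (default 31/28/32 subjects), 4D BOLD
   runs (TR 2.5 s, 200 volumes, 3 mm grid) built from region-wise
   equicorrelated signals (within-region correlation ρ per group, so the
   region's population NH equals ρ), rigid-body motion traces with drift and
   spikes, and a clinical table (HRSD-17, BAI, SHAPS-C, TEPS subscales) with a
   planted negative correlation between right-middle-temporal NH and TEPS
   scores.
2. **Preprocessing** — discard first 10 volumes, exclude subjects moving > 2 mm
   or > 2°, per-voxel linear detrend, zero-phase 0.01–0.08 Hz band-pass,
   nuisance regression (WM/CSF means + Friston-24 motion expansion; the global
   signal is preserved), framewise displacement (Power convention, 50 mm
   sphere).
3. **DMN mask** — group spatial ICA (two-stage PCA reduction, FastICA,
   dual-regression back-reconstruction), template-based component selection,
   per-group overlay at z > 1 into a binary mask.
4. **NH maps** — the statistic above on the mask, then 4 mm FWHM
   mask-renormalized Gaussian smoothing.
5. **Group inference** — voxelwise ANCOVA (three-group F) and pairwise t maps
   adjusting for age, education and mean FD; residual smoothness estimation;
   Gaussian-random-field cluster-extent correction (voxel p < 0.001, cluster
   p < 0.05); cluster tables with peak mm coordinates and labels.
6. **Clinical statistics** — ANOVA with LSD post hocs / pooled t / χ²
   reconstructed from printed summary cells or raw data; Pearson correlations
   between cluster NH and clinical scores with Benjamini–Hochberg correction.
7. **Classification** — leave-one-out SVM (RBF, C = 1, γ = 1/d, fold-wise
   standardization) over cluster-NH features, with an exhaustive subset search
   and accuracy/sensitivity/specificity reporting.

## Worked example

```python
from nhkit import RunConfig, run_pipeline

cfg = RunConfig(seed=20240901)
cfg.cohort.seed = 20240901
res = run_pipeline(cfg)

print(res.cluster_tables["melancholic vs nonmelancholic"]
      [["label", "n_voxels", "peak_stat", "p_corrected"]])
print(res.classification["best"])
```

prints:

```
    label  n_voxels  peak_stat  p_corrected
0   itg_l        60  -7.125542     0.000054
1  smfg_l        47   5.167167     0.000159
2  smfg_r        47   4.972833     0.000159
{'features': ('smfg_l', 'itg_l'), 'accuracy_pct': 88.14,
 'sensitivity_pct': 83.87, 'specificity_pct': 92.86}
```

Melancholic patients show lower NH than nonmelancholic patients in the left
inferior temporal gyrus and higher NH in the bilateral superior medial frontal
gyrus — the sign pattern planted by the generator — and the most
discriminative feature pair is left SMFG + left ITG. Among the melancholic
group, the right-MTG cluster's NH correlates negatively with TEPS total score
(`res.correlations`: r = −0.502, raw p = 0.004, BH-corrected p = 0.0195
across the cluster family).

A command-line interface wraps the same machinery:

```sh
nhkit simulate --out cohort/ --seed 1        # write NIfTI runs + rp files + TSV
nhkit preprocess --in cohort/ --out prep/    # per-subject QC JSON + cleaned runs
nhkit run --out run1/ --seed 1               # full pipeline, summary.md/json
```

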