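# dmnflow

Spatiotemporal analysis of the default mode network (DMN) in resting-state
fMRI cohorts, aimed at studies contrasting treatment-resistant schizophrenia
(TRS), treatment-responsive schizophrenia (non-TRS) and healthy controls (HC).
The package implements the full analysis chain as a tested, reusable library:

1. **Preprocessing** — Jenkinson framewise displacement (RMS displacement over
   an 80-mm sphere), mean-FD subject exclusion (> 0.2 mm), Friston-24 motion
   expansion, WM/CSF nuisance regression, zero-phase Butterworth filtering
   (0.01–0.1 Hz voxel-wise band-pass; 0.15 Hz network time-course low-pass),
   and 6-mm FWHM Gaussian smoothing.
2. **Group spatial ICA** — temporal-concatenation group ICA: per-subject PCA
   reduction, extended Infomax unmixing (natural gradient with sub/super-
   Gaussian switching), MDL (Wax–Kailath) model-order selection, and
   ICASSO-style stability analysis (repeated runs, |r| clustering, quality
   index Iq = mean intra-cluster − mean extra-cluster similarity).
3. **Subject metrics** — dual-regression back-reconstruction giving each
   subject's component time course, spatial map and a scalar *loading
   coefficient* (RMS amplitude of the fitted component time course);
   histogram Shannon entropy H = −Σ pᵢ ln pᵢ of the cleaned network time
   course; voxel-wise network homogeneity (NH: mean Pearson correlation of a
   voxel with all other network voxels) and voxel-wise entropy, with Fisher
   r-to-z / within-mask standardization.
4. **Inference** — ANCOVA partial-F group comparisons adjusted for age, sex,
   education and mean FD, Tukey HSD / Fisher LSD post hoc tests on adjusted
   means, Cohen's d via partial η², threshold-free cluster enhancement (TFCE)
   with Freedman–Lane max-statistic permutation FWE correction, and
   covariate-adjusted symptom regression.

Because subject-level imaging data from such studies are not generally
shareable, the package ships a first-class **synthetic cohort generator**
with known ground truth: a three-group cohort whose DMN-like source has a
group-graded loading (HC < non-TRS < TRS), a time-course marginal whose
excess kurtosis is graded the opposite way (so histogram entropy orders
HC > non-TRS > TRS), realistic motion, WM/CSF leakage, and a disorganization
score linearly coupled to the loading. Every stage is validated against this
ground truth.

## Worked example

```python
from dmnflow import PipelineConfig, run_pipeline

config = PipelineConfig(
    simulate=dict(group_sizes=(4, 4, 4), grid_shape=(16, 16, 16),
                  n_volumes=64, n_sources=3),
    n_components=3, n_runs=4, seed=0, output_dir="demo_out",
)
report = run_pipeline(config)
for metric in ("loading", "entropy"):
    r = report["stat_results"][metric]
    print(metric, "F = %.3f" % r["F"], "p = %.3f" % r["p"],
          "d = %.2f" % r["cohens_d"])
```

prints (12-subject demo cohort, seed 0):

```
loading F = 1.644 p = 0.283 d = 1.62
entropy F = 0.031 p = 0.969 d = 0.22
```

i.e. the ANCOVA group F-statistics for the DMN loading coefficient and
network entropy with their p-values and effect sizes — at n = 4 per group the
demo is underpowered, so large d estimates with non-significant p-values are
expected. `demo_out/` then contains `metrics.tsv` (one row per subject:
loading, entropy, mean FD, phenotypes), `group_components.nii` (the z-scored
group component maps), and `report.json` with the full provenance, the
exclusion log, post hoc tables and symptom-regression results. The same run
is available from the shell:

```bash
dmnflow run-all --out demo_out --n-components 3 --n-runs 4 --seed 0
```

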