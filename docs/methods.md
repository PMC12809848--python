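# Methods

This note documents the models, estimators and numerical choices behind
`dmnflow`, and what the synthetic-cohort validation does and does not
establish.

## The analysis model

The pipeline targets resting-state fMRI cohort studies that characterize one
intrinsic network — canonically the default mode network (DMN) — both
spatially and temporally, and relate the resulting subject-level metrics to
group membership (healthy controls, treatment responders, treatment-resistant
patients) and symptom severity.

Group spatial ICA assumes each subject's data matrix **X**ᵢ (time × voxel) is
a linear mixture of spatial sources shared across subjects. Subjects are PCA-
reduced in the temporal dimension (default: ⌈1.5 K⌉ components per subject,
K = model order), stacked along time, and unmixed by extended Infomax into K
spatial components. Dual regression then yields for each subject the
component time courses (regression of each volume on all group maps jointly,
with intercept, after voxel-wise temporal demeaning), the subject map
(regression of each voxel's series on the time courses), and a scalar
*loading coefficient*, defined here as the RMS over time of the component's
fitted time course. This scale is arbitrary but consistent across subjects;
group **contrasts** of loadings, not their absolute values, are the
scientifically meaningful quantity, and only contrasts are validated.

Temporal complexity is quantified as the histogram Shannon entropy of the
cleaned network time course: amplitudes are binned into `n_bins = 32`
equal-width bins spanning [min, max], and H = −Σ pᵢ ln pᵢ (nats), bounded by
ln 32 ≈ 3.47. Two properties are worth stating plainly: H is invariant to
affine rescaling of the series (the bins track the range), and it is
invariant to temporal reordering — it measures the *marginal amplitude
distribution*, not dynamics in the sequential sense, even though reduced
amplitude diversity is commonly read as reduced temporal complexity. The
implementation follows the literal histogram definition and the 32-bin
default was chosen so that typical entropies fall in the ~3 nat range
reported for real network time courses.

Network homogeneity (NH) assigns each voxel of a network mask the mean
Pearson correlation of its series with every other voxel in the mask,
computed from row sums of the correlation matrix (identical to the O(m²)
pairwise definition; the tests verify this to 1e-12). NH maps are
z-transformed by Fisher's atanh (r clipped at 1 − 1e-7); entropy maps by
within-mask standardization, since no canonical transform exists for
entropies. The network mask is derived by thresholding the group component
z-map at z ≥ 1 (configurable), mirroring the convention of displaying DMN
nodes at weak threshold.

## Preprocessing choices

* **Framewise displacement** uses the Jenkinson RMS formulation:
  FD_t = √(r²/5 · tr(AᵀA) + tᵀt) for [A|t] = M_t M_{t−1}⁻¹ − I on an 80-mm
  sphere, rotations composed Rx·Ry·Rz in radians. Subjects with mean FD
  above 0.2 mm (strict inequality) are excluded.
* **Confound model**: Friston-24 motion expansion (6 parameters, backward
  differences with a leading zero row, and both squared) plus caller-provided
  WM and CSF signals. Tissue-mask signal extraction is out of scope; in
  synthetic runs the generator's nuisance table provides these columns.
* **Filtering** is a zero-phase (forward–backward) Butterworth of order 4;
  only cutoff frequencies are standard in the literature, so family and
  order are documented defaults. Voxel-wise cleaning runs detrend →
  confound regression (the linear trend is kept in the regression so that a
  series lying in the design span is removed exactly) → 0.01–0.1 Hz
  band-pass. Network time-course cleaning runs detrend → despike → 0.15 Hz
  low-pass → confound regression.
* **Despiking** is deliberately simple and deterministic: robust z based on
  median/MAD with clipping at |z| > 3.5 to the boundary.
* **Smoothing** is a separable Gaussian with σ = FWHM/(2√(2 ln 2)) per axis
  in millimetres, handling anisotropic voxels per axis.

## ICA numerics

Extended Infomax is run full-batch with the natural-gradient update
W ← W + λ(I − D tanh(u)uᵀ/V − uuᵀ/V)W, D = diag(±1) re-estimated every
iteration from sign(E[sech²u]E[u²] − E[u tanh u]). Defaults: learning rate
0.2 with halving on divergence, convergence when ‖ΔW‖_F < 1e-6, at most 2000
iterations. The 2000-iteration ceiling was chosen because the tolerance is
routinely reached only after 500–1800 full-batch steps at these problem
sizes; tighter ceilings return usable but unconverged iterates with a
warning. Single runs occasionally land in poor local optima, so every
decomposition that feeds downstream analysis uses ICASSO aggregation:
repeated runs from fresh random states (voxel bootstrap optional), pooled
estimates clustered by average-linkage on 1 − |r|, the centrotype returned
per cluster, and Iq = mean intra-cluster − mean extra-cluster similarity.
Component sign is fixed so each map has positive skewness; maps are z-scored
over the mask. Model order, when not fixed by configuration, comes from the
Wax–Kailath MDL criterion on the temporal covariance eigenvalues.

## Group statistics

ANCOVA is the partial F comparing the full linear model (intercept + group
dummies, reference HC + covariates age, sex, education, mean FD) with the
covariate-only model; df = (k−1, N−k−c). Adjusted group means are model
predictions at the covariate grand means. Post hoc comparisons act on
adjusted means: Tukey HSD uses the studentized-range distribution with the
model's residual df (the default), Fisher LSD the unadjusted t — both are
provided because the two names are often conflated in applied reports.
Cohen's d for the group effect is derived via partial η² = F·df1/(F·df1 +
df2), d = 2√(η²/(1−η²)); this convention reproduces the conventional printed
effect sizes for three-group ANCOVAs and is documented as the package's
adopted definition.

Voxel-wise inference uses TFCE (H = 2, E = 0.5, dh = max/100, 26-
connectivity) with Freedman–Lane permutation: residuals of the covariate-only
model are permuted and added back to the covariate fit, the group partial-F
map recomputed, and the maximum TFCE value per permutation forms the null;
corrected p(v) = (1 + #{max ≥ TFCE(v)})/(n_perm + 1). Surviving voxels
(p < α) are reported only in clusters of at least `min_cluster` voxels
(default 10). Defaults: 5000 permutations, seeded.

## The synthetic cohort generator

The generator emulates the statistical structure of a three-group study
(defaults 64/76/48 subjects, 235 volumes at TR = 2 s): spatial sources are
sums of 2–4 spherical Gaussian blobs placed with ≥5σ separation so clusters
are effectively disjoint (the DMN surrogate gets midline-anterior,
midline-posterior and two lateral blobs); the DMN loading is drawn per group
from N(10.03/10.15/10.21, 0.28), matching the magnitude and spread of
reported loading tables; time courses are AR(1) (coefficient 0.4) modulated
by a slowly varying lognormal volatility process (AR 0.9) that sets the
marginal excess kurtosis exactly to the per-group target (0/1.5/4), which
yields cleaned-time-course entropies near 3 nats with an HC > non-TRS > TRS
gradient of realistic size (d ≈ 0.5). The volatility route was chosen over
independent heavy-tailed draws because isolated spikes would be removed by
the very despiking and low-pass steps the pipeline prescribes, and because
persistent variance excursions are how BOLD amplitude actually fluctuates.
Motion is a smoothed random walk scaled so cohort mean FD spans roughly
0.05–0.12 mm with group multipliers (1.0/1.15/1.3); WM/CSF signals leak
uniformly into the brain and one random spatial pattern follows the summed
motion, so nuisance regression has real work to do. Disorganization is
intercept + 4.241 × loading + N(0, 5.9), making the symptom slope a
recoverable planted parameter with borderline significance at realistic
sample sizes. Sex ratios are configurable and deliberately not matched to
any particular published table, whose internal counts are not fully
consistent. All randomness derives from one seed with fixed per-subject
substreams.

What the generator does **not** emulate: anatomy and registration error,
slice-timing and distortion artifacts, spatially structured physiological
noise, hemodynamic convolution, or non-stationary group differences in
network topography. Passing the recovery suites therefore shows that the
estimators are correct and well-calibrated under the assumed linear mixing
model — not that the pipeline is robust to every artifact of real data.

## Problem sizes used in validation

The validation suites run at deliberately small scales chosen to exercise
every code path with comfortable statistical margins: decomposition recovery
on a 12-subject, 16³-grid, 64-volume cohort; directional recovery of the
group gradients on twenty 36-subject cohorts (120 volumes) with 8-run
ICASSO; ANCOVA calibration on 1000 null simulations; permutation-FWE
calibration on 200 repetitions of 8×8×8 null maps with 300 permutations;
symptom-slope recovery on ten full-size phenotype cohorts.

## Known limitations

* Loading coefficients are on an arbitrary scale; only contrasts transfer
  across datasets or implementations.
* Histogram entropy ignores temporal ordering; sample/approximate/multiscale
  entropy variants are noted but not implemented.
* GICA3/GIG-ICA back-reconstruction variants are not implemented; dual
  regression is the single supported route.
* The MDL order estimate assumes approximately white residual noise; heavily
  colored noise biases the selected order upward.
* Real-atlas network templates and tissue-mask signal extraction are inputs,
  not products, of the pipeline.
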