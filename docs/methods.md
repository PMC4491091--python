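# Methods

## Model and pipeline

The object of study is the partial-correlation structure of 14 ROI time
series partitioned into three networks (6/4/4 regions). For each
subject the pipeline computes, for every unordered region pair (91 in
all: 15+6+6 within-network, 24+24+16 between-network), the Pearson
correlation of the two series after OLS-regressing each on the 12
remaining series plus an intercept. This is exactly the Gaussian-
graphical-model partial correlation −ω_ij/√(ω_ii ω_jj) of the sample
precision matrix; the test suite holds the two routes to 1e−8 of each
other on random data. Coefficients are mapped to Fisher Z = atanh(r)
per subject and averaged element-wise across subjects on the Z scale
(the variance-stabilized convention; averaging r first and transforming
after is deliberately not offered as a default, but `group_average`
accepts r-scale inputs and transforms them first).

Assumptions: series are approximately stationary after drift removal;
dependence is linear; the 14 regions jointly follow an (approximate)
multivariate Gaussian so that partial correlation captures conditional
dependence. Degrees of freedom for any single-coefficient inference
would be n − 12 − 2 after conditioning on 12 regressors and the
intercept; such per-edge inference is not part of the battery.

## Preprocessing

* **High-pass filter**, per run, cutoff 1/128 Hz: the run is regressed
  on a discrete-cosine basis containing the constant and every DCT-II
  cosine with period ≥ 128 s (k ≤ 2·N·TR·cutoff), and the residuals are
  returned with the original mean restored. This is projection, hence
  idempotent. A Butterworth filter would also work; the DCT convention
  matches the software family the cutoff value comes from.
* **First-run normalization**: each region of each later run is
  multiplicatively rescaled so its temporal mean equals the first run's
  mean for that region. This discounts global per-run signal-level
  differences. The alternative of matching variance too is available
  (`normalize_mode="zscore"`) but off by default: the stated purpose of
  the step is to equalize *global* signal levels, and variance matching
  would also erase genuine amplitude structure.
* **Concatenation** preserves run order. Order of operations is
  filter → normalize → concatenate, fixed: drift is run-specific, so
  filtering must precede pooling.

Filtering is applied to the sphere-averaged ROI series, not voxelwise;
the two commute for a linear filter and unweighted averaging.

## ROI geometry

Regions are 6-mm-radius spheres at MNI millimetre coordinates. A voxel
belongs to a sphere iff its centre is within the radius (≤, Euclidean,
in millimetres) — the simplest testable convention. Voxel indices are
0-based and the 4×4 affine fully defines the voxel↔MNI mapping; the
default synthetic grid is 3-mm isotropic (61×73×61, origin
(−90, −126, −72)), a common normalized-fMRI resolution. On that grid a
6-mm sphere holds 33 voxels (verified against brute-force lattice
enumeration). Extraction is the unweighted mean over sphere voxels; no
gray-matter restriction is applied.

## Statistical battery

* **Boundary effect**: one-tailed Welch t of the 27 within-pair versus
  64 between-pair group-level Z values, alternative within > between.
  The unit of observation is the region pair (the group matrix's SEM
  bars are over pairs); subject-level variants are retained in
  `NetworkSummary.subject_pair_values` for sensitivity checks.
* **Dunnett many-to-one**: per comparison a Welch t of the treatment
  group against the control; the family-wise adjusted p is the
  Monte-Carlo probability (default 100,000 draws, fixed internal seed,
  +1-corrected) that the maximum statistic across the family exceeds
  the observed one, with all groups resampled from one normal
  population at the observed sizes. The null distribution is cached per
  design, so repeated tests and calibration studies are cheap. The
  implementation is cross-checked in the tests against
  `scipy.stats.dunnett` (which it must approximate when group variances
  agree) but never delegates to it.
* **Tukey–Kramer**: pairwise |mean difference| / √(MSW/2·(1/n_i+1/n_j))
  referred to the studentized-range distribution with k groups and
  N − k degrees of freedom; reduces to √2·|t| for two balanced groups.
* **Preserved-pair test**: one-tailed one-sample t of the subject-level
  Z values for a single pair (n = group size) against the abnormal
  baseline Z = 0.052, alternative greater. No multiplicity correction
  is applied across the three preserved pairs; the battery reports raw
  p-values and significance thresholds are annotations only.

All two-sample tests use the Welch (unequal-variance) form. Every
test's Type-I error is calibrated on null simulations in the acceptance
suite (500 replicates, 5% ± 3.3 binomial σ).

## Synthetic data generator

The generator emulates the *structure* of the study's data so the whole
pipeline can be exercised against known truth:

* **Templates.** Planted Fisher-Z levels per pair category —
  normal: within 0.18 / between 0.002; leveled: uniform 0.045 or 0.052
  (the two patient groups' published overall means); other: three
  preserved edges (F3op/F3t–IPS 0.22, LPMC–AG 0.28, F3t–F3O 0.25) over
  a uniform 0.052 baseline. tanh maps planted Z to partial r.
* **Precision construction.** Ω has unit diagonal and ω_ij = −r_ij. If
  Ω is not positive definite, off-diagonals are shrunk by the largest
  λ ∈ (0,1] (bisection to 1e−6) achieving a minimum eigenvalue ≥ 1e−6,
  and λ is reported; all four study templates need no shrinkage
  (λ = 1), so the planted values are realised exactly.
* **Per run** (default 5 runs × 100 volumes, TR 2 s): correlated
  Gaussian noise with covariance Ω⁻¹; a task component — 6-s boxcars at
  onsets every 24 s convolved with a double-gamma HRF (peak delay 6 s,
  undershoot 16 s, ratio 1/6), peak-normalized, scaled by 0.2× the unit
  noise scale and added identically to all regions; a cosine drift of
  amplitude 1.0 and period 300 s with an independent random phase per
  region (period chosen below the 1/128 Hz cutoff so the filter removes
  it); a constant offset of 100; and a per-run global gain drawn from
  U(0.9, 1.1), which the first-run normalization must undo.
* **Seeding.** One master seed per group; per-subject streams are
  spawned via `numpy.random.SeedSequence`; reruns are bit-identical.
* **Volume rendering** (optional): each region's series painted
  uniformly into its non-overlapping sphere of a 4-D NIfTI over
  Gaussian background noise, to exercise the extraction path.

Run count, run length, and TR are this package's choices — the original
acquisition parameters are not public — so recovery tolerances
(±0.02 on category means at 7 subjects × 500 volumes) are defined
relative to these defaults. The shared task component is a deliberate,
mildly adversarial feature: with the default amplitude it inflates
partial correlations by < 0.01, within tolerance, and a
`remove_task_design` option regresses the design out first for
sensitivity analyses (default off, since the primary analysis
correlates the full filtered series).

What a green recovery test does **not** establish: robustness to
hemodynamic nonlinearity, physiological (cardiac/respiratory) noise,
head motion, lesion-induced signal dropout, or inter-subject
variability in the true connectivity structure — all subjects of a
synthetic group share one template, so between-subject variance is
sampling noise only, and the preserved-pair t tests are correspondingly
better powered than they would be on real patients.

## Numerical choices

* Collinearity in the regress-out step is detected by regressor-matrix
  rank and by residual norm ≤ 1e−8 of the column scale; both raise.
* Matrix symmetry is enforced to 1e−10; diagonals are stored as NaN and
  excluded from every summary (rendered black in heatmaps).
* The Fisher transform requires |r| < 1 and raises outside it.
* Monte-Carlo p-values use the (b+1)/(m+1) correction and so never
  return 0.
* Demographic summaries round as the source table does: means to
  integers, SDs to one decimal below 10 and to integers above.

## Known limitations

* The Dunnett Monte-Carlo null assumes equal group variances (it
  simulates a common population); with strongly heteroscedastic groups
  the family-wise adjustment is approximate even though each statistic
  is Welch.
* Pair-level tests treat the 27 + 64 group-level pair values as
  independent observations; pairs sharing a region are in fact weakly
  dependent. This follows the original analysis convention (pairs as
  the unit) and is one reason significance thresholds are annotations,
  not decisions.
* No regularized (shrinkage / graphical-lasso) estimator is provided;
  with 14 regions and ≥ 500 volumes the sample precision matrix is
  comfortably well-conditioned.
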