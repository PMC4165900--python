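# Methods note

`funconn` analyzes resting-state functional connectomes: per-subject ROI
time series are turned into Pearson connectivity matrices, binarized over a
sparsity regime, summarized by graph metrics and their area under the curve
(AUC), and compared between two groups with FDR-corrected mass-univariate
statistics. A synthetic-cohort generator with known ground truth stands in
for real fMRI data throughout testing.

## Preprocessing

Input is a T×N ROI time-series matrix plus optional 6-column rigid-body
motion parameters (3 translations in mm, 3 rotations in rad). Cleaning
order: censor → regress → filter (the common resting-state convention).

- **Framewise displacement (FD).** Scalar Power-style FD: the sum of
  absolute backward differences of the six parameters, rotations converted
  to arc length on a **50 mm** sphere. FD of the first frame is 0. Frames
  with FD > **0.5 mm** are deleted (no interpolation; correlation
  estimation tolerates unequal T). A run shrinking below `min_frames`
  (default **100**) raises `InsufficientDataError` rather than silently
  producing unstable correlations.
- **Confound regression.** The Friston 24-parameter expansion
  [R, R(t−1), R², R(t−1)²] of the motion parameters, plus any user-supplied
  T×K confounds, are removed by ordinary least squares with an intercept.
  Collinear design columns are detected by QR rank and dropped (logged at
  debug level). Tissue-signal regressors do not exist at ROI level for
  synthetic data, so the confound interface is a generic matrix.
- **Band-pass filter.** Zero-phase ideal (FFT mask) filter, default
  **0.01–0.08 Hz**, the standard resting-state band; band edges must lie
  below Nyquist.

## Connectivity and binarization

Pearson correlation over all N(N−1)/2 region pairs (90 regions → 4005
pairs). A graph at sparsity *s* keeps the K = round-half-up(s·N(N−1)/2)
pairs with the largest **signed** r (an `absolute=True` option ranks by
|r|); ties are broken deterministically by ascending region-index pair, so
edge sets are nested across the grid and runs are reproducible. Default
regime: **0.10–0.34 in steps of 0.01** (configurable; the regime bounds are
not legible in the source literature, so they are explicit parameters).

## Graph metrics (from scratch, binary undirected)

Distances by breadth-first search. Global: clustering coefficient Cp
(mean of 2tᵢ/(kᵢ(kᵢ−1))), characteristic path length Lp over **finite**
pairs only (raises if no finite pair exists), global efficiency (mean of
1/d, with 1/∞ = 0), local efficiency (mean global efficiency of each
node's neighbour subgraph). Nodal: degree, nodal efficiency, and Brandes
betweenness normalized by (N−1)(N−2)/2. All seven are tested against
closed forms and an independent reference implementation (networkx is a
test-only dependency).

## Null models and small-world parameters

Degree-preserving Maslov–Sneppen rewiring: **10 swaps per edge** with an
attempt cap of 10× the target, skipping swaps that would create self-loops
or duplicate edges. Normalized parameters over `n_rand` (default **100**)
surrogates: γ = Cp/⟨Cp_rand⟩, λ = Lp/⟨Lp_rand⟩, σ = γ/λ. A graph is called
small-world when γ > 1, |λ−1| ≤ 0.15 and σ > 1. If every surrogate has
zero clustering the null is degenerate and the normalized values are
undefined (`ValueError`; the curve sweep records NaN at that sparsity).
Note the per-realization spread: a single Erdős–Rényi graph's clustering
can differ from its degree-conditioned null mean by ~20%, so calibration
checks average γ/λ/σ over several realizations.

## Group statistics

- **Edge-wise:** per pair, Fisher z-transform, covariate residualization
  (design: intercept, age, sex as 0/1, education, and the three pairwise
  interactions; residuals restored to the original mean), Welch t-test
  (pooled optional), BH-FDR in a single family over all pairs.
- **Global / nodal AUC:** each metric curve is summarized by its trapezoid
  AUC over the sparsity grid, covariate-residualized, Welch-tested. FDR
  families: all global metrics together; per nodal metric across regions.
  A region is "abnormal" if any of its three nodal metrics is significant.
  Under-determined designs on small groups are reduced column-by-column
  (and abandoned with a warning if even the intercept-only fit is
  impossible); metrics with undefined values (e.g. degenerate-null γ) are
  excluded from their FDR family.
- **Behavior:** plain pairwise Pearson correlation between each abnormal
  region's nodal AUCs and each clinical score, **within the patient group
  only**, BH-FDR over all (region, metric, score) triples. Covariate
  adjustment is available (`adjust_covariates=True`) but off by default:
  it residualizes only the metric side, and with ~17 patients a 7-column
  design absorbs ~6/16 of the variance by chance, sharply attenuating true
  correlations.
- **Demographics:** Table-1-style comparison — Pearson chi-square (2×2,
  no continuity correction) for sex, two-sample t-tests elsewhere. The
  t/χ² statistics accept either raw samples or printed (n, mean, sd)
  summaries so published tables can be checked directly.

BH-FDR uses `statsmodels`; t and χ² p-values use `scipy.stats`
distributions; least squares uses `numpy.linalg.lstsq`.

## Synthetic cohort generator

Each group's N×N correlation target is a modular block matrix: `r_within`
(default **0.4**) inside consecutive modules, `r_between` (default
**0.08**) across, unit diagonal. Planted edges (i, j, δ) shift group B's
entry by δ. If the matrix is not positive definite, |λ_min| + 1e−6 is
added to the diagonal and the matrix rescaled to unit diagonal. Subjects
are i.i.d. Gaussian draws via Cholesky; subject k uses seed + k, so
extending a cohort never reshuffles existing subjects. Motion is Gaussian
jitter (0.02 mm, 2e−4 rad) with 2% spike frames of 1 mm. Demographics and
the six clinical scores default to the study population's distributions.

**Score coupling.** A score with nonzero slope is generated as
intercept(group) + slope · AUC(nodal metric, region) + noise, where the
AUC is computed from the subject's *own simulated series* over
`score_grid` (default 0.10–0.34, step 0.04) — the same summary the
behavior test analyzes. A noise-free "true" metric derived from the group
covariance would be constant within a group, making within-patient
correlation recovery meaningless; the per-subject values used are stored
in `ground_truth.json`, which analysis stages never read.

**Scope.** The generator emulates statistical structure, not physiology:
no hemodynamic response, spatial smoothness, physiological noise spectra,
or realistic motion coupling to signal.

## Calibration studies (`funconn.studies`)

Scaled study size chosen to finish in minutes on one CPU: 17 vs 16
subjects, **20 regions** in four modules, 210 timepoints, 7-point grid
(0.10–0.34, step 0.04), 6 surrogates per sparsity for γ/λ/σ.

- *Null calibration:* 20 cohorts with no group difference → edge, nodal
  and global pipelines should reject (almost) nothing.
- *Planted recovery:* 20 cohorts with three cross-module edges at
  |δ| = 0.4 → the edge-wise test should recover all three.
- *Correlation recovery:* YIAS coupled to region 5's nodal-efficiency AUC
  with slope 400 and noise SD 1 (signal:noise ≈ 3:1, planted r ≈ 0.96 —
  chosen by power analysis: detection through an 18-triple BH family at 17
  patients needs r ≳ 0.75). Coupled cohorts must flag exactly that triple;
  slope-0 cohorts must not (allowing ≤1 chance rejection across replicates,
  consistent with the family-level false-positive rate).

## Limitations

- Binary graphs only; weighted analysis, partial correlation and
  p-value-thresholded graphs are out of scope.
- The γ/λ/σ estimates at very sparse, small graphs are often undefined
  (degenerate nulls) and are reported as NaN rather than extrapolated.
- The synthetic generator's realism is limited to second-order structure;
  effect sizes measured on it do not transfer to real fMRI.
- Calibration rates are Monte-Carlo estimates at fixed seeds and problem
  sizes; they are checks of internal consistency, not empirical claims
  about any real population.
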