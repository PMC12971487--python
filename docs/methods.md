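# Methods

This note records the models, conventions and numerical choices behind
`devgeo`, and what the synthetic validation does and does not establish.

## Measurement model

A subject's condition-by-voxel response pattern for one run is modeled as

    P = S + I_subject + R_run + E,

where `S` is the group-shared signal (common to every subject of a
cohort), `I` is an individual component (common to a subject's runs), `R`
is a session component (common within a run, shared by its two repetition
halves) and `E` is i.i.d. measurement noise per half. `S` itself is
`L Z + sigma_group * G`, with `Z` a standard-normal basis, `G`
unstructured shared noise, and `L` the matrix square root of the target
covariance `C = Σ_k w_k M_k` built from hypothesis RSMs `M_k` with mixture
weights `w_k`. Consequently the expected cross-subject pattern covariance
equals the planted mixture, and cross-subject similarity analysis is
estimating a known quantity.

Two conventions deserve emphasis:

- **PSD flooring by diagonal shift.** Hypothesis matrices with ±1 weights
  are strongly indefinite (the category model's smallest eigenvalue is
  −31). `C` is floored by adding |λ_min|·I rather than clipping
  eigenvalues: the shift preserves every off-diagonal entry of the
  planted mixture exactly and reads as added stimulus-specific signal
  variance, whereas clipping silently distorts the similarity structure
  being planted. The cost is attenuation: with the category model the
  planted correlation contrast is ≈ 2/32 per entry, which is in line with
  the small group-RSM magnitudes characteristic of cross-subject
  correlation RSMs.
- **Shared basis across linked cohorts.** The realized `S` of a cohort is
  one draw; two cohorts generated independently from the same mixture do
  *not* have rank-correlated RSMs beyond the tie-limited ceiling of the
  hypothesis matrix. Cohorts meant to share representational geometry
  (age groups of one population, longitudinal timepoints) must be
  generated on the same `structured_basis`.

Head motion is hierarchical-lognormal: a run's mean FWD is lognormal
around the group mean (σ = 0.8 on the log scale; group means 0.912, 0.532
and 0.177 mm for young infants, older infants and adults), and frames are
lognormal around the run mean (σ = 0.5). Between-run spread is essential:
it is what motion binning and importance reweighting operate on. Spike
artifacts are injected into frames whose FWD exceeds the censoring
threshold.

What the generator does **not** emulate: spatial voxel correlation,
hemodynamic nonlinearity, susceptibility distortion, slice timing, or any
infant-specific anatomy. Passing recovery tests therefore shows the
estimators are correct under the additive model, not that they are robust
to every artifact of real infant data.

## First-level GLM

OLS per voxel on a design with HRF-convolved condition boxcars (Glover
double-gamma, peak 6 s, undershoot 16 s, ratio 1/6 — the canonical
defaults), one single-1 spike column per censored frame (FWD > 1.5 mm),
six motion covariates, a linear trend, unit-norm cosine drifts below
0.01 Hz and an intercept. Spike regression of frame f is algebraically
identical to deleting row f, and the residual degrees of freedom shrink by
one per spike because each spike column absorbs exactly one frame; both
facts are asserted in tests. Runs with more than 50% of frames censored
are rejected. Per voxel, the dispersion proxy is
max over condition regressors of [(XᵀX)⁻¹]_cc × residual mean square; the
max is the conservative aggregation (the per-regressor rule is also
available via `condition_dispersion`), and voxels above 10 are masked.
Rank deficiency is detected by pivoted QR and reported with the offending
column names. tSNR is temporal mean over detrended temporal s.d., averaged
over ROI voxels, with zero-variance voxels excluded and counted.

## Cross-subject RSMs and reliability

Pair RSMs are computed only across subjects (at run level, within-subject
pairs are excluded; adults are aggregated to one unit per subject before
pairing — the aggregation level is configurable per group). Entries are
centered Pearson correlations, symmetrized over the two orderings, with
the diagonal left as the cross-measurement same-condition correlation.
The group RSM is the (optionally weighted) mean; a blocked Gram-matrix
implementation makes large cohorts cheap and is tested for exact
agreement with the pairwise loop. Display z-scoring standardizes entries
without changing rank structure.

The noise ceiling is the split-half reliability of the group RSM: subjects
are partitioned into random halves (runs travel with their subject), the
Spearman correlation of the two half-RSM upper triangles is averaged over
100 splits, and the Spearman–Brown step-up 2r/(1+r) is applied to the mean
raw correlation. Below a floor of 0.1 the ceiling is flagged unreliable
and correlations are reported un-normalized — dividing by a near-zero
reliability would manufacture arbitrarily large "normalized" effects.

## Inference

RSA statistics are Spearman correlations of vectorized upper triangles;
the diagonal is included for perceptual/categorical models and excluded
for network layers and maturity (both conventions are flags). Partial RSA
rank-transforms everything, residualizes brain and model ranks on the
covariate ranks by least squares, and correlates the residuals; degenerate
covariates are dropped, and collinearity of the model with its covariates
is an error.

Bootstrap inference resamples units with replacement, averages them into a
group RSM and applies the statistic; CIs are percentile 95% intervals of
1,000 resamples by default. Two unit choices exist, and they answer
different questions:

- **Pair resampling** treats pair RSMs as units. This mirrors the
  published procedure, but pairs sharing a subject are dependent, and the
  measured effect is that pair-resampled CIs understate the
  subject-sampling s.d. of the pair average by roughly 2.4× on synthetic
  cohorts.
- **Subject resampling** (`bootstrap_statistic_subjects`) draws whole
  subjects and recomputes the multiplicity-weighted pair average
  (same-subject duplicates contribute no pair). This is the calibrated
  choice, and the one used in the coverage experiment.

The coverage experiment itself is designed around two validity
constraints. First, the estimand must be the *cohort-conditional* value
given the realized shared signal — no subject bootstrap can resample the
single realization of `S`, so the unconditional mixture value is not the
right target. Second, the statistic must be linear in the group RSM (the
least-squares mixture weight), because a Spearman statistic either
saturates (zero sampling variance once the model's similarity levels
separate perfectly) or carries convexity bias, and either failure mode
confounds a calibration experiment regardless of how the CI is built.
Under those constraints (40 subjects, 500 voxels, measurement σ = 3 so
sampling variance dominates the O(1/V) error of the conditional
expectation formula), subject-resampled percentile CIs achieve ≈ 95%
empirical coverage; the acceptance suite requires ≥ 88% over 100
replicates.

A corollary worth stating plainly: **rank-correlation RSA does not order
generative mixture weights.** With a planted mixture of category (w = 1)
and animacy (w = 0.5), the noiseless Spearman correlations are 0.64 vs
0.95 (diagonal included) — the animacy model's larger blocks saturate the
rank statistic. Weight ordering is recovered by the joint least-squares
regression of the group RSM on the model set
(`recover_mixture_weights`), which returns (1.0, 0.5) exactly in the
noiseless limit and recovers the ordering in ≥ 95% of replicate cohorts
at the reference size. Correlation-based profiles remain the right tool
for *comparing a single model across groups*; they are not comparable
*across models* with different block structure.

Motion matching bins runs by mean FWD on decile edges of the pooled
source+target sample (unique-value bins when the pooled sample has few
distinct values) and weights source units by target/source bin counts.
When the target's motion range is well represented in the source
(e.g. reweighting the youngest infants to the older-infant distribution),
the reweighted mean FWD matches the target mean within 10% (observed
≈ 1%). Reweighting toward a target far outside the source's bulk (adult
motion from infant runs) shifts the mean most of the way but cannot reach
it — the matched quantity there is the agreement *between* reweighted
groups, not agreement with the unreachable target.

The longitudinal test permutes the linkage between timepoints; the
p-value uses the add-one Monte Carlo rule, and its null distribution is
verified approximately uniform (KS test across 100 replicate cohorts).

## Variance partitioning

Covariance-metric RSMs (patterns condition-mean-centered first) are
additive over independent components, so the mean trace over three
comparison tiers identifies nested variances: across-subject pairs →
group; within subject across runs → + individual; within run across
repetition halves → + session. Traces are divided by (n_conditions − 1),
which exactly undoes the shrinkage that condition-mean centering applies
to an isotropic component, so an injected variance σ² is recovered as σ².
The subtraction scheme (group = T₁, individual = T₂ − T₁, session =
T₃ − T₂) is this package's reconstruction of the three named comparisons;
it is validated by recovery (injected 1.0/0.5/0.25 recovered within a few
percent at 40 subjects × 2 runs × 500 voxels) and components are reported
unclipped, so sampling noise can make them negative. The category-level
variant splits each category's six within-run events odd/even and fits a
24-regressor GLM, the only same-run comparison that avoids correlating an
estimate with itself.

## Network alignment

The default provider is a seeded, Glorot-initialized, never-trained
convolutional stack with five convolution stages (ReLU; max-pool after
stages 1, 2, 5) and three fully connected stages, the classic eight-layer
object-recognition geometry scaled to a 128×128 input (64×64 in tests)
for single-CPU use. Stimuli are composited on a mid-gray background
(128/255). Activations are captured post-ReLU and flattened; pretrained
models are supported through activation files only. Layer RSMs are
Pearson correlations between image activation vectors.

Layer identifiability is the weakest recovery problem in the package:
untrained-network layer RSMs are mutually correlated (adjacent-layer
Spearman up to ~0.83) with small off-diagonal spread, while the realized
shared signal carries entrywise jitter ~1/√V that correlation scaling
cannot reduce. At the 500-voxel reference cohort the planted-layer argmax
is recovered in roughly 85–95% of replicates depending on the draw
(~98% at 2,000 voxels); the acceptance suite's frozen-seed run measures
90%.

## Embeddings

Metric SMACOF (Guttman transform, uniform weights) with per-iteration
monotone raw stress, initialized by Torgerson classical scaling by
default — random initialization regularly stalls in poor local minima
even on exactly embeddable inputs, classical scaling is exact there.
Dissimilarity is max(M) − M with the diagonal zeroed, a rank-preserving
transform. Hierarchical alignment fits one global configuration on the
mean dissimilarity, then refines per region, then per region×age, each
stage warm-started from its parent (never re-randomized); majorization
guarantees each refinement's stress is no worse than evaluating its
parent's configuration. Stress-1 = √(raw stress / Σd²) is reported.

## Problem sizes and defaults

Synthetic validation uses 36 conditions (12 categories × 3 exemplars),
40 subjects per group and 500 voxels for recovery and calibration
experiments, 20–100 replicates depending on the experiment, 1,000
bootstrap resamples for reported CIs (300 inside replicate loops), and
100 noise-ceiling splits. Thresholds keep their analysis defaults
throughout: FWD 1.5 mm, 50% censored-frame rejection, dispersion 10,
ceiling floor 0.1, 10 FWD bins. The full test suite runs in about a
minute on one CPU; `scripts/acceptance.py` in about one minute.

## Known limitations

- Additive Gaussian patterns without spatial structure; recovery results
  do not certify robustness to spatially correlated artifacts.
- The diagonal-shift PSD floor attenuates planted contrasts; analyses of
  strongly indefinite models at low voxel counts are jitter-limited (see
  network alignment above).
- Pair-resampled bootstrap CIs mirror the published procedure but are
  anticonservative for subject-level generalization; use subject
  resampling when coverage matters.
- The deposited-derivative pickle reader is exercised on synthetic
  fixtures only.
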