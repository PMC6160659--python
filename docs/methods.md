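# Methods

## The analysis

`ecmap` implements eigenvector centrality mapping (ECM) of resting-state
BOLD fMRI and the group-inference chain built on top of it.

**Centrality model.** For a run with N masked voxels and T volumes, every
voxel's time series is mean-centered and scaled to unit L2 norm, so the dot
product of two rows of the resulting N×T matrix M is their Pearson
correlation r. Voxelwise connectivity is the shifted correlation

    C = R + 1,   C_ij = r_ij + 1 ∈ [0, 2],

which is non-negative, so by the Perron–Frobenius theorem the dominant
eigenvector of C is strictly positive and well defined as a per-voxel
centrality score. Since C = M Mᵀ + J (J the all-ones matrix), the power
iteration evaluates C·v as M(Mᵀv) + (Σv)·1 in O(N·T) per iteration without
materializing the N×N matrix. Because J contributes a dominant rank-one
term of magnitude N, the spectral gap is large and the iteration converges
in a handful of steps; on random normalized data (N = 500, T = 325) it
stays well under 100 iterations at the default tolerance.

Centrality is computed inside the intersection of all single-subject
masks (a voxel is in a subject's mask when the temporal minimum of its
series is positive), so the network's node set is identical across
subjects. Two maps are produced per subject: one from the high-pass
filtered data, one with the six realignment parameters additionally
regressed out voxelwise (the "motion-regressed" variant).

**Group inference.** The group contrast (carrier vs noncarrier) is fitted
voxelwise by OLS with gender, age, normalized gray-matter volume and the
Framingham index as nuisance covariates. Inference uses permutation of the
group labels (covariates fixed) with cluster mass — the sum of |t| over a
connected suprathreshold component — as the test statistic. The
cluster-forming threshold is chosen automatically as the candidate value
that maximizes the mean number of suprathreshold clusters over the null
(permuted) maps, both contrast directions counted, ties broken toward the
larger threshold. The cluster-mass significance threshold is the smallest
null mass m with count(null masses ≥ m)/n_permutations ≤ 1, i.e. at most
one expected false-positive cluster per image. The analysis is run twice
(with and without motion regression) and the final cluster mask is the
direction-matched intersection of the two sets of significant voxels.

**Association and prediction.** Per subject, the motion-regressed
centrality is averaged inside the cluster mask. Each marker (age, CSF
amyloid, NGMV, 15-object-test score, trail-making A/B times) is related to
the cluster mean by simple linear regression on the whole sample and
within each genotype stratum; a one-way ANOVA tests the group effect.
Prediction of carriership uses unpenalized maximum-likelihood logistic
regression (IRLS), evaluated by leave-one-out cross-validation, with a
tie-aware ROC/AUC and a stratified percentile bootstrap for the AUC 95%
interval; a second model adds age as a covariate.

## The synthetic cohort

No data accompany the analysis, so the package ships a generator that
emulates the study's statistical structure. Defaults mirror the study
scale: 261 subjects, 29% risk-allele carriers, 325 volumes at TR 1.82 s on
a 4 mm isotropic grid (the grid itself is desk-scale, 20×20×12 voxels).

Each subject's BOLD is built from band-limited (0.01–0.1 Hz) Gaussian
latent signals on a positive baseline of 100:

- six disjoint cuboid **communities** (the hub placed posterior), each
  driven by its own latent signal;
- a shared **global signal** loaded by every community voxel (base loading
  0.5) and weakly by the background (0.2) — no voxel is pure noise, and the
  hub's centrality depends on its coupling to the whole network;
- the **hub community** loads the global signal additionally with
  1 − deficit·group, so carriers' hub connectivity to the entire network is
  reduced by the configured fractional deficit;
- unit-variance white noise everywhere.

All loadings carry independent per-subject lognormal jitter (sd 0.25 on
the log scale). This heterogeneity is essential for realism in two
directions at once: without it, carriers and noncarriers separate almost
perfectly even at small deficits (no biomarker behaves that way), and the
tiny uniform shift that unit-norm centrality redistributes from the hub to
the rest of the brain becomes hyper-significant off-hub because nothing
else varies between subjects. A mild fractional deficit (~0.15) under this
jitter yields the "above chance, below 0.75" single-subject separability
regime the method is expected to show; the recovery simulations use a
strong deficit (0.8).

Markers are generated as marker = mean + slope·z + noise, where z is the
standardized true hub loading, so the sign of each configured slope is the
sign of the marker's correlation with hub centrality. Default signs: age
negative, CSF amyloid positive, NGMV negative, 15-object score and both
trail-making times positive; every sign and noise level is configurable.
Gender is Bernoulli(151/261 female); age is Normal(56.6, 6.7) truncated to
[39, 80]; MMSE is 28–30 (screening floor of the cohort).

Motion traces are cumulative-sum random walks in the six rigid-body
parameters with a per-subject lognormal scale (sd 0.4), summarized by a
framewise-displacement-style statistic (mean L1 translation step plus
50 mm times the L1 rotation step); with the default step size about 3% of
subjects exceed the 0.5 mm exclusion threshold, matching the study's 8/269
exclusion rate in order of magnitude. A configurable fraction of subjects
(default 20%) loses the top two axial slices, exercising the
intersection-mask logic that partial-coverage acquisitions require.

What the generator does **not** emulate: spatial smoothness and
registration artifacts, physiological noise spectra, scanner drift beyond
what the high-pass filter removes, anatomical geometry, and any
deliberate correspondence to the real cohort's fitted coefficients.
Passing tests therefore demonstrate correctness and calibration of the
algorithms under the assumed generative structure, not performance on
real acquisitions.

## Numerical choices

- **High-pass filter**: regression on a discrete-cosine drift basis; the
  k-th regressor has period 2·T·TR/k, and the order is
  K = floor(2·T·TR/cutoff) (K = 6 at the default 182 s cutoff with T = 325,
  TR = 1.82 s). Output is mean-zero per voxel. A cutoff admitting no
  regressor degrades to demeaning with a warning.
- **Motion regression**: OLS on [intercept, six parameters]; residuals are
  returned with the voxel mean added back; collinear columns are dropped
  with a warning.
- **Zero-variance voxels** are removed from the analysis mask before
  normalization (correlation is undefined there); the group analysis uses
  the mask intersection across subjects after this screen.
- **Power iteration**: uniform positive start vector 1/√N; stop when
  successive unit vectors differ by < 1e-9 in max-norm (cap 1000
  iterations, convergence flagged).
- **Connectivity entries** are r + 1 exactly — no rescaling by N or T;
  eigenvectors are invariant to positive scaling of C.
- **Clusters**: 26-connectivity by default (6/18 configurable); positive
  and negative directions clustered separately and pooled into one null
  mass distribution; mass is Σ|t| (not the excess over the threshold).
  Candidate forming thresholds: |t| = 1.5 to 5.0 in steps of 0.1. On
  spatially unsmoothed maps the null cluster count typically keeps growing
  toward the low end of this grid, so the automatic rule tends to select
  1.5; with smoothed maps it selects an interior value.
- **Permutations**: simple relabeling of the group column with covariates
  fixed; the null distribution is permutations-only (the observed map does
  not contribute). Default 1000 permutations; every seed is explicit.
- **Logistic regression**: IRLS on internally standardized features
  (constant features drop to the intercept), tolerance 1e-10 on the
  standardized coefficients, cap 100 iterations. Quasi-separation is
  flagged when coefficients run away while the fit saturates; predictions
  remain usable (saturated). Classification threshold for accuracy: 0.5.
- **Bootstrap**: 2000 stratified replicates by default (class counts
  preserved, so no degenerate single-class resample), percentile 2.5/97.5
  interval.

## Design choices where the procedure was open

- The automatic forming threshold maximizes the **mean** null cluster
  count over permutations (maximum and total are the alternatives; the
  mean is the stable choice at modest permutation counts).
- The marker table's group-adjusted column reports the marker term's p in
  a model containing marker + group; a marker×group interaction variant is
  available behind a flag. No multiple-testing correction is applied to
  the primary p-values; a Bonferroni column is emitted as supplementary
  output.
- The prediction model is plain unpenalized maximum likelihood. (The
  elastic-net machinery that a penalized-regression package would bring is
  deliberately not replicated; with the penalty off, the two coincide.)
- Subject exclusion is by the motion summary alone (threshold 0.5 mm);
  other real-world exclusion reasons are representable through a generic
  per-subject `usable` flag in the phenotype table.

## Known limitations

- Leave-one-out held-out probabilities of a *null* predictor are
  anti-predictive by construction (removing a positive subject tips the
  training fit against it), so their AUC sits below 0.5. This is a
  property of LOOCV, not a defect of the AUC computation; chance-level
  calibration of the bootstrap interval is therefore assessed on scores
  that are independent of the labels.
- The ≤1-expected-false-positive mass rule controls the expected count,
  not the family-wise error rate; single null images can contain more
  than one significant cluster.
- An empty intersection cluster mask is a valid outcome (the pipeline
  reports it and skips association/prediction); at the default subtle
  deficit and desk-scale grid this happens for some seeds.
- Simulation-heavy checks run at desk scale — 40 subjects, 150 volumes,
  20×20×12 grid, 200 permutations for the calibration and recovery
  studies — chosen so the whole suite runs on a laptop-class single CPU.
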