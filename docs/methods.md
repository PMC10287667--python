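# Methods

This note records the model implemented by the package, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not demonstrate.

## Maturational-network estimation

Input is a cohort of K subjects, each an N-voxel × T-timepoint matrix on a
shared grid, with gestational age (weeks) per subject. The voxel order is a
single source of truth: the lexicographic rank of the (x, y, z) lattice
index; every N-length vector in the package uses it.

**Dense connectomes and the age regression.** Each subject's N×N Pearson
matrix is regressed element-wise across subjects on the design
[intercept, age]. We accumulate Σy, Σy², Σ(a·y) per element with centred
ages, giving slope β = S_ay/S_aa, residual SS = S_yy − β²·S_aa, and
t = β/se with df = K−2, exactly equal to per-element OLS (verified to
1e-8 against looped fits). Correlations are regressed as raw r; a
`fisher_z` flag applies the variance-stabilising transform at the cost of
changing β's units (per-week change in z rather than in r). Framewise
displacement is deliberately not a covariate in the default design: the FD
analysis (below) supports treating the age–motion association as
collinearity rather than confounding; an FD-covariate mode exists for
sensitivity analyses. Elements with zero residual variance receive ±inf
sentinels, are flagged, and are zeroed on entry to the factorisation with a
logged warning. The diagonal is structurally constant and set to zero.

**Thresholding.** "Thresholded at 0" is implemented as clamping negatives
to zero while keeping the dense shape. This keeps only age-related
*increases* in coupling, which is the signal the factorisation should
explain; the negative local component produced by age-shrinking smearing is
discarded by construction.

**Reduction.** The thresholded matrix is streamed column-block-wise through
an incremental SVD: concatenate the first two blocks, reduce to rank R,
append the next block, reduce again, until exhausted. Retained rows are
weighted by their singular values so that each subsequent SVD sees correctly
scaled variance (the unweighted variant is a flag). Defaults are 200 blocks
and R = 500, with R capped at N/4 on small grids. With data of rank ≤ R the
result spans the exact top right-singular subspace; otherwise it is the
standard MIGP approximation.

**Spatial ICA.** Fixed-point ICA with the logcosh contrast and symmetric
(parallel) decorrelation over the voxels-by-components view of the reduced
data, tolerance 1e-6, 1000 iterations, up to 5 differently-seeded restarts
derived from one seed. Output maps are z-scored over the mask (plain
mean/sd; no mixture-model calibration), sign-fixed to non-negative skewness,
and ordered by explained variance of the reduced data. Non-convergence in
every restart raises an error from an estimator that still carries the best
attempt; `strict=False` downgrades this to a warning. The escape exists
because on noise-dominated data the sources approach Gaussianity and the
fixed point can cycle above any practical tolerance irrespective of the
starting point (we observed cycling at 1000 iterations across 12 restarts
even at tol 1e-4); diagnostics that depend on the component subspace rather
than a certified rotation (the bias analysis below) run with the escape.

## Downstream constructs

**Emerging-connectivity profiles.** Each column of the thresholded
maturational dense connectome is regressed on the demeaned matnet maps plus
an intercept. The intercept/demeaning convention makes slopes
covariance-scaled and sends an all-zero column to all-zero slopes. Row m of
the resulting M×N matrix is matnet m's complementary map.

**Maturational connectome and embedding.** Pairwise Pearson correlations
between profile rows form the M×M maturational connectome. The affinity for
the spectral embedding is the positive part of the off-diagonal correlation
(the similarity reading; negatives are weak in rich data). On toy problems
with few components the profile correlations can be predominantly negative,
leaving a degenerate graph; the `(1+r)/2` affinity is provided for that
regime. Coordinates are eigenvectors of the symmetric normalised Laplacian
L = I − D^(−1/2) W D^(−1/2) for the three smallest strictly positive
eigenvalues, unscaled by default (a 1/√λ diffusion-style scaling is a
flag). Disconnected affinity graphs beyond dim+1 components and isolated
nodes are errors. Note that a 3-D embedding cleanly separates up to four
groups; with very few networks the third eigenvector may already encode a
within-group contrast.

**Partition and hubs.** Ward linkage on the embedding coordinates; the
group count G is the finest cut in {2..M} producing no singleton group,
falling back to G = 1. Hub maps are the first right singular vector of each
group's complementary maps after centring each map over voxels; the sign is
aligned to the group-mean map. Per-map centring (rather than subtracting
the mean map) keeps a group of identical maps well defined: its hub is that
map with explained variance 1.

**Coupling trajectories.** Matnet and complementary map are thresholded at
z > 5 to reduce overlap; per subject the two z-weighted average timecourses
are correlated and the couplings regressed on age with a polynomial whose
order is selected by BIC over {1, 2, 3}; the confidence band on the mean
trajectory is reported at α = 0.05.

## Reference pipeline and diagnostics

Group ICA: per-subject voxelwise variance normalisation (flag), temporal
concatenation streamed through the incremental SVD with subjects as blocks,
then the same spatial ICA. Dual regression: spatial regression of each
timepoint on the demeaned group maps, variance normalisation of the
resulting timecourses (flag), then temporal regression per voxel.
Mass-univariate age modelling reuses the streaming OLS. The bias diagnostic
is the spatial correlation between each group map and its age-effect t-map.

A relevant analytic fact surfaced in testing: for a pure-noise subject the
expected dual-regression stage-2 map equals the group map itself with
spatial correlation ≈ 1/√(1 + N/T) — the self-leak of voxels contributing
their own noise to the stage-1 timecourses. It vanishes only as N/T grows
large (the regime of real acquisitions) and always exceeds a naive spatial
permutation null; the test suite asserts the derived level rather than a
permutation band.

Univariate diagnostics: seed-to-brain group means are averaged on raw r
(Fisher-z averaging is a flag); parcel-pair map similarities include the
seed voxels (exclusion is a flag); connected components use
26-connectivity; FD summaries are per-parameter, per-stack mean absolute
first differences (richer denoising expansions are out of scope), columns
standardised across subjects before the PCA, PC1 sign-aligned to row-mean
motion.

## Synthetic cohorts

The generator is latent-first: P non-negative Gaussian-blob network maps
(optionally mirror-symmetric bilateral), latent timecourses drawn per
subject with covariance Σ(age) = baseline + slope·(age − 25), projected
onto the maps, plus spatially autocorrelated Gaussian noise. Σ(age) is
checked for positive definiteness at every sampled age. The noise kernel
FWHM decreases linearly with age (default 6 mm at 25 w to 2 mm at 38 w,
2 mm voxels), emulating the larger common-space smearing of smaller brains
— the period covers a roughly three-fold growth in brain size — and is
applied to the noise only by default, with a switch to smear the full
series. An optional motion factor with target r(age, motion) = −0.25
drives one-factor random-walk motion traces (6 parameters × 16 stacks).

Defaults: a 16×16×12 grid with an ellipsoidal mask (N ≈ 1600 voxels),
P = 5 networks, two emerging edges (0,1) and (2,3) at 0.045/week (taking
the latent correlation from 0 to ≈ 0.59 across 25–38 w), one age-stable
network, noise sd 0.5 against blob peaks of ≈ 1–2, K = 60 subjects with
evenly spread ages, T = 100 timepoints. These sizes keep the full pipeline
in tens of seconds per run while leaving every planted effect comfortably
detectable; they are configuration, not claims about any real cohort, whose
effect sizes and noise levels are unknown to us.

Two condition variants are fixed for specific validations:

* the **bias-mechanism cohort** uses noise sd 0.7 and full-series smearing,
  the regime where smeared local structure dominates the correlational
  signal (as it does in utero); with the default shrinking kernel the
  median map/age-effect correlation is ≈ −0.5, with an age-invariant 4 mm
  kernel it is ≈ 0 — the mechanism check;
* the **distance-similarity cohort** uses noise sd 1.5, a gentler 5→3.5 mm
  kernel gradient and a ring of emerging edges so every network carries
  distal age structure; there the distance dependence of group-mean seed
  maps (r ≈ −0.8) exceeds that of age-effect maps (r ≈ −0.7), reproducing
  the ordering of the two effects, not their real-data gap.

What passing these tests shows: the estimators recover exactly the
structure the generator plants, under the noise model it assumes
(Gaussian, stationary per subject, no haemodynamics, no scanner artefacts,
perfect registration). They do not validate performance under real fetal
artefact regimes, registration error, or vascular confounds.

## Numerical conventions

Ages are centred before accumulation; correlation matrices are clipped to
[−1, 1] and symmetrised exactly; zero-variance voxels/rows are flagged and
zeroed, never dropped; zero-variance motion columns are dropped with a
warning, with an error if all are constant; k-means parcellation
(k-means++, fixed seed) retries with a new seed on an empty parcel;
Ward cuts that are unreachable due to ties are skipped in the G search;
NIfTI maps are written in float64 so round trips are exact; dense matrices
are stored as row-chunked HDF5 with mask hash, K and df in attributes.

## Known limitations

The age model is linear per element (polynomials appear only in coupling
trajectories); no multiple-testing correction is applied to age-effect maps
by default (a BH-FDR utility is provided); the full-scale defaults
(200 blocks, R = 500, M = 25) follow the method's large-N regime and are
untested here at N > a few thousand voxels; anatomical naming of networks
and hubs is out of scope.
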