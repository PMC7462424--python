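# Methods

`betanet` implements a task-evoked functional-network topology analysis:
trial-level beta-series connectivity, signed-modularity consensus
clustering, allegiance-based community and region inference, and
data-driven selection of the structural resolution parameter. Because the
pipeline is exercised on synthetic cohorts with planted community
structure, this note describes both the analysis model and what the
generator does and does not emulate.

## Task and synthetic-cohort model

The modeled experiment is an event-related two-condition comparison task:
80 trials per condition, intermixed and pseudo-randomly ordered so that no
more than 3 consecutive trials share a condition or a numerosity
(numerosities {2, 4, 6, 8}, counterbalanced), 500-ms stimuli, ISIs drawn
from {3,300 … 7,300} ms in 1,000-ms steps (mean 5,300 ms), counterbalanced
over conditions and numerosities, sampled at TR = 2 s. Order generation is
constrained random construction with restarts (capped at 10,000); any
constraint-satisfying order is accepted, since the original randomization
algorithm is not specified by design descriptions of such tasks.

Each subject's regional activity follows a one-factor-per-community trial
amplitude model. For a trial in condition *c* with planted partition
*M_c*, region *i*'s amplitude is

    x_i = sqrt(rho_w) u_{M_c(i)} + sqrt(1 - rho_w) eps_i,
    u_k = sqrt(rho_b / rho_w) g + sqrt(1 - rho_b / rho_w) h_k,

so trial-level correlations are `rho_w` within and `rho_b` between
communities (defaults 0.6 / 0.1, in the range typical of task-evoked
beta-series correlations). Amplitudes are convolved with a canonical
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6, truncated at 32 s,
unit peak) on the TR grid; Gaussian volume noise of SD `sigma_noise`
(default 1.0, i.e. equal to the trial-amplitude SD) and an i.i.d.
per-volume censor mask (default rate 0.04, matching the ~4% censored
volumes typical of well-behaved cohorts) complete the subject record. A
fast path (`generate_connectivity_cohort`) skips time series and samples
connectivity matrices directly as planted block matrices (blocks at
`atanh(rho) * sqrt(N - 3)`) plus symmetric Gaussian noise.

What the generator does **not** emulate: autocorrelated physiological
noise, spatially structured motion artifacts, inter-subject variation in
HRF shape or community topography, hubs and gradients of connectivity
strength, and negative *true* coupling (negative weights arise only from
sampling noise). Passing recovery tests therefore demonstrates the
correctness and calibration of the estimation and inference machinery
under the stated generative model, not robustness to every property of
real fMRI data.

`sample_condition_partitions` additionally emulates subject-level
partition variability directly (label-flip noise, default 0.2–0.25, which
reproduces group allegiance values around the 0.6–0.9 range seen in real
group matrices) with *partial penetrance* of planted membership changes
(default 0.5): each subject expresses each planted change with that
probability. Full penetrance makes every affected community's profile
trivially significant; partial penetrance reproduces the weak group-level
reconfigurations the region-level analysis is designed to detect.

## Beta-series estimation

Trial betas are estimated with the least-squares-separate (LS-S) scheme:
per trial, an OLS GLM with the trial's HRF regressor, one combined
regressor summing all other trials, optional nuisance covariates, and an
intercept. Censored volumes are removed by row deletion per trial GLM.
Rank-deficient trial designs (e.g. a fully censored trial) yield missing
betas, treated as scrubbed. A trial is scrubbed when its response span —
`ceil((onset + 13.1)/TR) − floor(onset/TR)` volumes — contains ≥ 2
censored volumes.

A subtlety worth recording: with a *single* combined other-trials
regressor, heterogeneous other-trial betas cannot be fit exactly even in
noiseless data, and the misfit couples into the trial coefficient through
the shared intercept (≈ 0.1–0.2% relative error with disjoint regressors,
a few percent with densely overlapped trials). The estimator is exact
whenever the trial model spans the data (any 2-trial design) and unbiased
in expectation otherwise; tests assert exactly these three regimes.

Betas are normalized per region within condition to mean 0, SD 1 over
retained trials. The SD convention is population (divide by n), the usual
pattern-analysis choice; `ddof=1` is available. Connectivity is the
pairwise Pearson correlation over retained betas (listwise per condition),
Fisher-Z transformed and scaled by `sqrt(N − 3)` into z-scores, with |r|
clamped at `1 − 1e-12`, zero diagonal. Scrubbed trials are excluded
listwise, one retained set per condition.

## Signed modularity and consensus clustering

The quality function is Q* with asymmetric treatment of negative weights:

    Q* = (1/v+) Σ_ij (w+_ij − γ e+_ij) δ_ij − (1/(v+ + v−)) Σ_ij (w−_ij − γ e−_ij) δ_ij

with per-sign strengths `s±_i`, totals `v± = Σ_ij w±_ij`, configuration
null `e±_ij = s±_i s±_j / v±` (zero when `v± = 0`), and resolution γ.
Positive weights count at full scale; negative weights are down-weighted
by the total weight — the standard treatment for functional networks where
negative correlations have a different interpretive status.

Maximization is a generalized two-phase Louvain on the dense modularity
matrix `B = (W+ − γE+)/v+ − (W− − γE−)/(v+ + v−)`: greedy node moves in a
seeded random order (ties broken toward the lowest community index, so
runs are seed-stable), then community aggregation, repeated to a fixed
point. The returned Q* is re-evaluated exactly from the definition on the
final partition. Partitions are canonicalized by first appearance so
equality is structural.

Subject-level pipeline: 1,000 Louvain runs (100 during sweeps) → allegiance
matrix (fraction of runs co-assigning each pair) → consensus clustering:
threshold at τ = 0.5, re-partition 100 times, rebuild agreement, iterate
(≤ 50 rounds, convergence error otherwise; components disconnected by the
threshold may become singletons). Group level: the across-subject
allegiance matrix (fraction of subjects co-assigning a pair) is
consensus-clustered with the same procedure and the same τ. The consensus
re-clustering of agreement matrices always runs at γ = 1 regardless of the
analysis γ — agreement matrices are nonnegative co-assignment frequencies,
and re-using a high analysis resolution would fragment perfect agreement
blocks. Labels between condition partitions are matched by optimal
assignment on the contingency table; unmatched communities keep fresh
labels.

## Resolution selection

The γ grid is 0.05–5.0 in steps of 0.05 (100 values). Partition stability
is tracked as mean pairwise normalized variation of information
(VI = H₁ + H₂ − 2·MI, natural logs, normalized by ln n; the base cancels)
among group partitions within a ±0.35/2 γ window (±3 grid steps; the
pipeline auto-sizes the window to 7 grid steps when the grid is coarser).
Between-condition flexibility is the binary per-region indicator of a
changed (label-matched) community assignment; the working γ* maximizes the
across-region sample SD of flexibility, averaged over index-matched repeat
pairs (the repeat-pairing convention is not canonical; index matching is
used), with ties broken toward smaller γ. The SD of a binary vector is
maximal at half flips, so γ* is the scale balancing stable and changing
assignments. On its original cohort this heuristic selected γ = 2.45;
that number depends on the deposited fMRI data and is not reproducible
from synthetic cohorts — the package's tests instead verify that γ* lands
at the planted expression scale (the block-separation transition) within
one grid step.

## Community-level inference

`Q_c*` is a community's additive contribution to Q*: both double sums
restricted to node pairs inside the community with the full-network
normalizers, so contributions over any partition sum exactly to its Q*.
Communities are screened by the mean over subject networks of Q_c* on the
group community's region set against `n_null` (default 1,000; 50,000-scale
runs are configurable) size-matched uniformly random region sets, selected
at the 99th percentile. The random-set null is one of several reasonable
nulls (the alternative is network rewiring); it is isolated behind a
single function so it can be swapped.

Within/between-community allegiance differences use the vector of
below-diagonal group-allegiance values per community pair, compared across
conditions with a paired t statistic (simple difference when a community
pair has a single region pair). The null swaps each subject's condition
labels with probability 1/2 (exchangeable under the no-difference null),
rebuilds both group matrices, and recomputes the statistics; defaults
50,000 iterations (reducible in configs). z = (T − μ_null)/σ_null;
two-tailed p with the add-one convention (so p is never 0 and the nominal
5% level is attainable when (n_perm + 1) · 0.05 is an integer);
Benjamini–Hochberg FDR over the k(k+1)/2 tests. Identical matrices are a
degenerate case returning z = 0, p = 1 with a warning.

## Region-level inference

A region's allegiance profile is its group-allegiance row (self entry
excluded; by symmetry each counterpart contributes once). Dissimilarity
between conditions is the *negated* Fisher Z of the profile correlation,
so larger = more dissimilar; zero-variance profiles (a region alone in its
community in every subject) are missing and excluded from counting at that
step. Per γ step the same subject-relabeling null (default 10,000
iterations; 99–200 in test configs) yields a one-tailed p for
greater-than-null dissimilarity; per region the number of steps with
p < 0.05 (uncorrected) is counted over the grid. Because any relabeling
null is a weighted average of fixed per-subject co-assignment matrices,
these are precomputed once per step and the null reduces to matrix
products.

Counts over regions are fit by maximum-likelihood negative binomial
(size–probability parameterization, mean profiled out; bounded 1-D
optimization from a method-of-moments start), falling back to Poisson at
the under-dispersion boundary (variance ≤ mean) and to a point mass for
constant samples. Outlier regions are flagged when the QQ residual
(observed sorted count minus fitted quantile at Hazen positions
(i − 0.5)/n) exceeds 2 × the IQR of residuals *and* the upper-tail
probability p_obs = P(X ≥ count) is below 0.05 — an implementable
surrogate for a visual QQ judgement, with both knobs configurable.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng` with explicit
  per-stage seeds; identical configurations give bit-identical run
  reports (SHA-256 over the canonical report JSON).
- Louvain move tolerance 1e-12; Fisher clamp `|r| ≤ 1 − 1e-12`; matrix
  symmetry tolerance on I/O 1e-8.
- The scrubbing span formula above covers 7–8 grid volumes at TR = 2 s
  (the conservative grid-aligned cover of a 13.1-s response).
- Default problem sizes in tests and the analysis drivers (6–33 subjects,
  24–202 regions, 4–100 γ steps, 99–2,000 permutations) were chosen so
  each check isolates one property at the smallest scale where its
  expected behavior is unambiguous; the full-scale settings (1,000
  subject-level iterations, 50,000/10,000 permutations, 100-value grid)
  remain the configuration defaults where they matter.

## Known limitations

- The generator's noise model is white; real beta-series noise is
  temporally and spatially structured, so real-data power will differ
  from synthetic calibration.
- LS-S betas are unbiased but not exact under overlapping responses (see
  above); connectivity built from them inherits that approximation.
- The consensus procedure can in principle fail to converge on adversarial
  agreement matrices; it then raises carrying the last agreement matrix
  rather than guessing.
- Permutation p-values are granular at 1/(n_perm + 1); small test-scale
  configs trade granularity for speed.
- The community-selection null (size-matched random region sets) is a
  design choice; rewiring nulls may select differently on networks with
  strong degree structure.
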