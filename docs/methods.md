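# Methods

## The phenotypes and their acquisition model

The package treats two layers of social phenotype derived from one data
stream. At the *event* level, every flocking event a bird takes part in
contributes one observation of group size (the number of distinct birds
in the event, including the focal bird). At the *weekend* level, events
within a sampling period are pooled into a group-by-individual matrix,
association weights are computed, and each bird gets one value per
period per network trait (mean group size, degree, strength, eigenvector
centrality, weighted eigenvector centrality, betweenness). The study
design being emulated has 13 weekend periods per winter over three
winters, hence 39 period networks.

### Event detection

Visits are segmented independently per feeder per day. The gap rule
starts a new event whenever the inter-visit gap exceeds `gap_seconds`
(default 600 s). The mixture rule fits 1-D Gaussian mixtures to the
day's visit times for k = 1..k_max components, keeps the best BIC, and
assigns each visit to its maximum-responsibility component; a richer
mixture is accepted only if it improves BIC by at least 10 (roughly
"strong evidence" on the deviance scale), which curbs the tendency of
BIC to shatter tight bursts into several components. Two further
choices make the output well-defined: responsibility ties go to the
lower-index component, and contiguous runs in time are taken as events,
so events at one feeder can never overlap even when mixture components
interleave. The mixture detector is a deliberately simple stand-in for
full variational event extraction; its accuracy is assessed against
ground-truth labels (pairwise co-assignment agreement, a Rand-type
index pooled within feeder-days) rather than against any particular
reference implementation.

### Network metrics

Association defaults to the simple ratio index
SRI = n_AB/(n_A + n_B − n_AB); raw co-occurrence counts are available by
flag. Degree and strength are row statistics of the weight matrix.
Eigenvector centrality is the leading eigenvector of the adjacency,
computed per connected component (it is undefined across components),
weighted by the square root of the component's leading eigenvalue and
then globally scaled to a maximum of 1; isolated nodes score 0.
Betweenness uses the binarised graph with unit edge lengths and
Brandes-style counting with equal-path splitting, endpoints excluded —
the "number of shortest paths through the node" reading. Weighted
betweenness variants were considered and rejected as under-specified for
association weights (a weight is an affinity, not a length).

## Relatedness

The additive relationship matrix A (twice the kinship; diagonal 1 + F)
is built by the tabular method over the topologically sorted pedigree.
Individuals named only as parents are auto-inserted as founders, which
is how immigrant breeders enter a field pedigree. Pruning keeps a focal
set plus all pedigree ancestors; because A entries depend only on shared
ancestry, pruning never changes relatedness among retained birds (this
is tested). Unknown-parent tokens ("", NA, 0, \*, .) are configurable.
A gene-dropping simulator (two unique founder alleles per individual,
Mendelian transmission, IBD sharing averaged over replicates) provides
an independent Monte-Carlo estimate of A used purely as a test oracle;
agreement is checked elementwise within 3 Monte-Carlo standard errors.

## Natal similarity matrices

Spatial proximity: s_ij = 1 − d_ij/d_max on Euclidean natal-nestbox
distances (planar site coordinates; the site is small enough that
geodesy is irrelevant), diagonal 1. Environmental similarity: the five
natal-environment variables (altitude, edge-distance index, northness,
oak density within 75 m, square-root territory size) are z-scored
(population SD) and the Euclidean distance in the standardised 5-space
is rescaled by the same 1 − d/d_max transform — chosen for internal
consistency with the spatial matrix, since distance-to-similarity
conversions differ across the literature; the transform is explicit and
configurable in the code. Neither construction is guaranteed positive
semi-definite, so both are routed through eigenvalue clipping (floor at
1e-8, reconstruct, rescale diagonal to 1) before use as covariances;
clipping preserves structure better than ridging, whose option remains
available. The Frobenius distortion of the repair is recorded on the
returned matrix.

## The REML engine

The model is y = Xβ + Σₖ Zₖuₖ + e with uₖ ~ N(0, Kₖσ²ₖ) and
e ~ N(0, Iσ²ₑ). Each structured term is transformed through a factor
Lₖ (Cholesky; eigen square root when Kₖ is singular) so all solves use
identity-level algebra. All per-iteration computation lives in the
q-dimensional level space via the Woodbury identity
(C = G⁻¹ + ZᵀZ/σ²ₑ), costing O(q³ + nq) per iteration with n
observations and q total random-effect levels — an n of 10⁵ with a few
thousand levels is routine.

* Starting values: the OLS residual variance split equally over the k
  random terms and the residual — scale-free and reproducible.
* Iteration: one EM step first (monotone, safe far from the optimum),
  then average-information (AI) steps with step halving; if no fraction
  of the AI step improves the restricted likelihood, EM is used for that
  iteration. Accepted steps therefore never decrease the likelihood.
* Constraints: components are non-negative. During iteration a
  component is clamped at a small floor (1e-8 of the raw phenotypic
  variance) rather than being removed — with collinear covariance
  structures (e.g. spatial vs environmental similarity) an early
  overshoot can park a component at zero that the likelihood later
  wants back, so permanent in-loop pinning is deliberately avoided.
  Only after convergence are components below 1e-6 of the raw variance
  declared boundary terms: reported as exactly 0, recorded in
  `boundary`, excluded from the information matrix, with SEs reported
  as unavailable.
* Convergence: |Δ log-likelihood| < 1e-8 and maximum relative component
  change < 1e-7 on two consecutive iterations (so a single heavily
  damped line-search step cannot fake stationarity), within 200
  iterations; non-convergence flags the result rather than silently
  returning it.
* Uncertainty: SEs from the inverse AI matrix at the optimum; ratio SEs
  (repeatability, h²) by the delta method over the full component
  covariance. The denominator of every ratio is the sum of the fitted
  components (no fixed-effect variance term).
* Likelihood-ratio tests compare nested REML fits (identical fixed
  effects required) against χ²₁ by default; the ½χ²₀ + ½χ²₁ boundary
  mixture is available and halves the p-value. Under the null the
  default test is conservative (empirical rejection ≈ 2–3% at α = 5%),
  which the calibration test asserts as an upper bound.

Degenerate inputs behave predictably: a model with no random terms
reduces to the closed-form REML residual (RSS/(n−p)); a genetic term
with an identity A is aliased with the individual term and the fit
matches the reduced model in likelihood and in the summed component
(tested); aliased fixed-effect columns are dropped with a warning via
pivoted QR.

## Model ladders

Event-level group size: Model 1 (ID), 2 (ID+A), 3 (LOG), 4 (ID+LOG),
5 (ID+LOG+A), fitted per winter and pooled with winter year as a fixed
factor. Weekend network traits: Models 1–2 only, since birds are
observed across multiple feeders a logger term is not meaningful.
Natal ladder, restricted to locally-born birds with known natal section
and brood: a (ID), b (ID+A), c (ID+SECT), d (ID+BI), e (ID+SECT+BI),
f (ID+A+SECT+BI, plus LOG for group size only), g (ID+A+SPATIAL),
h (ID+A+ENVSIM), i (ID+A+SPATIAL+ENVSIM). Birds absent from the
pedigree either enter A as unrelated founders (default) or are dropped,
by configuration — the field situation this mirrors is birds observed
at feeders that never bred locally. Each ladder model reports component
estimates, SEs, proportions of V_P (summing to 1 by construction), the
derived repeatability/heritability, and an LRT against its natural
reduced partner within the ladder.

## The synthetic-data generator

The generator emulates the structure of the study system, not any
particular data set: a multi-generation pedigree with monogamous pairs,
Poisson brood sizes and a configurable fraction of parentless
immigrants per cohort; a woodland of nestboxes on a jittered grid split
into 9 rectangular sections, with the five environment variables drawn
as exponential-covariance Gaussian fields (default range 300 m) over
box locations; 65 feeder loggers on a subgrid (desk-scale profiles use
fewer); and phenotypes

y_ij = μ + year_j + a_i + pe_i + log_l(ij) + sect_s(i) + bi_b(i) + sp_i + env_i + e_ij

with a drawn through a factor of A, sp/env through factors of the
(repaired) similarity matrices, and the rest i.i.d. Default variances
emulate the reported structure of winter group size in this system —
V_ID = 0.20, V_LOG = 0.30, V_A = 0.02, V_SECT = 0.01, V_BI = 0.02,
V_SPATIAL = 0.03, V_R = 0.42 of a unit V_P — so a default run shows the
qualitative pattern of interest: moderate individual repeatability, a
large feeder share, a small genetic share, and a few percent of natal
spatial structure. Broods map to natal boxes (so
siblings share natal environment), winter home loggers are chosen near
the natal box with Gaussian dispersal (SD 400 m), and each bird's
observations fall at its home logger with probability 0.8.

The visit stream couples loosely to the phenotype layer: events arrive
per logger per sampling day (the day window is partitioned into as many
slots as events, keeping events separated), groups are sampled from the
birds homed at that logger with weights increasing in a latent
gregariousness, and members leave 1+Poisson visits scattered around the
event centre. What the stream does *not* emulate — movement between
feeders within a day, temporal autocorrelation of group composition,
weather — means detector and network tests demonstrate algorithmic
correctness on plausible burst structure, not robustness to every field
artefact; likewise the generator's Gaussian phenotypes mean the REML
tests validate estimation, not the adequacy of a Gaussian model for
counts (group size is analysed untransformed, as in the study design
being emulated; a log flag exists).

## Problem sizes used in the checks

The test suite and acceptance script choose desk-scale sizes as their
study conditions: parameter recovery uses ~1000 focal birds with 20
observations each over 50 replicates (bias bound 0.03, coverage within
[0.88, 0.99]); the common-environment experiment uses ~900 locally-born
birds per replicate over 20 replicates; LRT calibration uses 500 null
replicates of 30×4 layouts; relatedness and network oracles use 25 and
50 random instances respectively. The acceptance script runs a lighter
12-replicate recovery and a 200-replicate calibration inside a single
three-winter study emulation.

## Known limitations

* The mixture detector over-segments long busy days relative to ground
  truth (co-assignment agreement ~0.93–0.96 on labelled streams, vs 1.0
  for the gap rule on well-separated events); both remain above the 0.9
  working threshold under 5× separation-to-spread.
* Indirect genetic effects, multivariate models, random regression and
  Bayesian fitting are out of scope.
* The natal similarity matrices share structure with brood identity and
  section by construction (siblings have spatial similarity 1), so
  their shares are only separable jointly, exactly as in the motivating
  analysis; the ladder reports all terms together rather than claiming
  orthogonal decomposition.
* SEs at pinned boundaries are unavailable by design; ratios involving
  pinned components carry the remaining terms' uncertainty only.
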