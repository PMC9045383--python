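# Methods and design notes

This note documents the models, the synthetic study design, the
numerical choices, and the places where the design was genuinely open.
Nothing here states an empirical result that the tests or
`scripts/acceptance.py` do not themselves compute.

## The synthetic cohort

The generator (`microdyn.synthetic`) emulates a small enclosed-habitat
crew study: `n_subjects = 4` (alternating male/female), 18 time points
per subject split `(5, 8, 5)` over three phases — outside, inside the
shared habitat, outside again — roughly matching a design with about a
month of sampling on either side of a longer enclosed stay and about 70
samples in total.

**Communities.** A global heavy-tailed abundance profile is drawn
log-normally (σ = 1.5) over `n_otus = 200` taxa, so a few taxa dominate,
as in real 16S surveys. Each subject's baseline community is a Dirichlet
draw with concentration 40 × profile: the low total concentration makes
baselines strongly person-specific (between-subject Jensen–Shannon
distances around 0.6–0.7), mirroring the strong individuality of
salivary microbiota. A single *shared-environment* community is drawn
the same way; subject *s* at time *t* has expected composition

    (1 − w_t) · base_s + w_t · shared,

with `w_t = shared_weight_inside` (default 0.5) for inside-phase samples
and 0 otherwise. This mixing weight is the convergence signal the
downstream analyses detect; at 0 the subjects are fully independent.

**Noise and counts.** Per-taxon log-abundance noise is stationary AR(1)
with coefficient `ar1_phi` (default 0 — the stationary, trendless regime
the study's stability analyses assume) and marginal sd 0.4. Optional
linear trends are added on the composition scale and the simplex
renormalized. Sequencing depth is log-normal with mean 33,820 reads and
CV 0.3 (matching a realistic clean-tag distribution with minima near
17k); counts are multinomial.

**Tree and taxonomy.** A random rooted binary tree is built by
recursively bisecting the ordered OTU list (exponential branch lengths,
floor 0.05), so contiguous OTU blocks form coherent clades; the block
taxonomy assigns 10 OTUs per genus and 4 genera per phylum. Genus-level
aggregation therefore has phylogenetic coherence without simulating
sequence evolution.

**Air sources and the unknown pool.** Air source communities (and the
"novel" community behind the unknown fraction in
`generate_air_and_sink`) get their *own* independent heavy-tailed
profiles. This matters: communities drawn around the same profile as the
sinks are intrinsically confusable with them, and source attribution
becomes ill-posed regardless of estimator. Air and host communities
differ systematically in reality; the generator encodes that.

**Cytokines.** A linked cytokine is `exp(sign · z + ε)` where `z` is the
subject-wise standardized log relative abundance of the linked genus and
`ε ~ N(0, sd)`; the exponential keeps concentrations positive without
disturbing rank correlations (noiseless links give Spearman ρ = ±1
exactly). Unlinked panel members are iid log-normal. Defaults plant
three links with distinct signs (TNF-α ~ G01 +, IL-10 ~ G03 −,
IL-1β ~ G05 +).

**What the generator does not emulate:** sequencing error and chimeras,
OTU-clustering artifacts, taxon-taxon interactions, seasonal or dietary
covariates, and compositional zero-inflation beyond what multinomial
sampling induces. Passing tests therefore demonstrate correctness of the
statistics under a clean generative model, not robustness to upstream
bioinformatic noise.

## Reference-community normalization

Steps: (i) fractional normalization per time point; (ii) abundant-OTU
selection — OTUs ranked by median-across-time fractional abundance, the
smallest prefix whose medians reach 90% of the summed medians;
(iii) per-time-point rescaling toward a reference. For focal time point
*t*, every other time point *u* gets weight `(1 − j(t,u))²`, with
`j` the Jensen–Shannon distance between the renormalized abundant-OTU
subcompositions. The reference value of each abundant OTU is the
weighted median over `u ≠ t` (smallest value whose cumulative weight
reaches half the total).

Numerical choices:

- **JSD uses base-2 logarithms**, so `j ∈ [0, 1]` and `(1 − j)²` is a
  proper similarity weight; `0·log 0 := 0`.
- **The final rescaling rule** — how the reference converts into
  corrected abundances — is the median of reference/observed ratios over
  abundant OTUs with nonzero observed fraction, applied multiplicatively
  to the whole time point. This median-ratio rule is the robust standard
  for size-factor estimation and makes a constant series an exact fixed
  point (all scale factors 1).
- If every other time point is maximally dissimilar (all weights 0), the
  reference falls back to equal weights rather than failing.

The method's purpose is bloom robustness: under a 10× single-OTU count
spike, the other abundant OTUs' fractions are restored toward their
unspiked values strictly better than fractional normalization alone
(asserted in the tests on a 20-OTU, 12-time-point simulation).

## Stationarity and trend testing

- ACF: biased (denominator-*n*) estimator on the mean-centered series —
  the conventional correlogram — with white-noise band ±1.96/√n. The
  stationarity verdict is "at most 5% of lags 1..L outside the band";
  the study-scale default is L = 5 for 18-point series.
- Mann–Kendall: exact S, tie-corrected variance
  `[n(n−1)(2n+5) − Σ_t t(t−1)(2t+5)]/18`, continuity-corrected normal
  approximation (appropriate at n ≈ 8–18), two-sided p. Direction is the
  sign of S regardless of significance, since "an increasing tendency"
  is reported in such studies even when not significant.
- Core OTUs: detected (count > 0) at strictly more than half of a
  subject's time points.
- Horizon transform: mean-centering plus band index
  `ceil(|x − mean| / MAD)` with MAD the mean absolute deviation — the
  data side of horizon graphs; rendering is out of scope.

## Convergence analysis

Weighted UniFrac is computed by postorder accumulation of per-branch
descending mass (identical to brute-force per-branch summation, and
cross-checked against scikit-bio); the normalized variant (bounded in
[0, 1]) is the default since phase-level distance comparisons need a
scale-free quantity.

**Why per-time-point means.** The natural display — violins of all
between-subject pairwise distances per phase — is fine descriptively,
but feeding those pooled pairs to a Kruskal–Wallis test
pseudo-replicates badly: each sample participates in several pairs and
each subject pair recurs at every time point. In null simulations
(mixing weight 0) the pooled-pairs test rejected at far above nominal
level, entirely from this dependence. The test implemented in
`diversity.convergence_test` instead reduces each time point to its mean
between-subject distance — conditionally independent across time points
given the baselines — and groups those summaries by phase (5/8/5
values). Null simulations then reject at ≈ the nominal 5%, and the
shared-environment signal at mixing weight 0.5 is detected with the
inside-phase median lowest. Pooled pairwise distances remain available
(`between_subject_distances`) and are reported alongside.

## Group separation

PCA is mean-centered, unscaled (fractions are already on a common
scale), computed by SVD with a deterministic sign convention. Separation
uses the first `min(25, available, N − k − 1)` PCs — the cap keeps the
pooled within-group covariance invertible on small cohorts — with a
ridge of 1e−8 × trace/dim for numerical safety. The overall statistic is
Wilks' Λ with Rao's F approximation; pairwise tests are Hotelling's T²,
Bonferroni-adjusted; cluster structure is single linkage on the
group-mean Mahalanobis matrix (whose merge heights equal the MST edge
weights, an identity the tests exploit as an oracle). The choice of
Wilks over Pillai is recorded in the output metadata; with two groups
they coincide.

## Source tracking

Model: sink counts are multinomial with probabilities
`Σ_k α_k β_k + α_u β_u`; known-source distributions β_k are the
pseudocount-smoothed (+1) source relative abundances.

**Why two stages.** Jointly re-estimating the unknown distribution β_u
each M-step is degenerate: `α_u = 1` with β_u equal to the empirical
sink is the global likelihood optimum, so the flexible unknown slowly
absorbs the known sources — slowly enough to look like convergence, and
catastrophically when the true unknown fraction is large. Dirichlet
priors on β_u delay but do not remove the collapse at realistic depths.
The estimator therefore:

1. fits α by EM with β_u fixed at uniform (deterministic, uniform α
   init);
2. forms the sink's *excess* composition: observed taxon fractions minus
   the fitted known-source mixture, thresholded at `residual_z = 1`
   multinomial standard deviation (so pure sampling noise does not
   masquerade as unknown community) and renormalized — uniform if no
   excess remains;
3. re-fits α by EM with β_u fixed at that excess (a well-posed convex
   mixture fit).

Each stage is a proper EM, so its log-likelihood is nondecreasing at
every iteration (asserted at run time); the reported trace is stage 2's.
Convergence: `max |Δα| < 1e−6`, at most 1000 iterations per stage. An
oracle check (β_u fixed at the true unknown composition) recovers the
design proportions of the dominant-unknown calibration essentially
exactly, confirming the two-stage estimator addresses an estimation —
not an identifiability — problem. `residual_z` was calibrated on the
generator's three canonical designs (exact two-source mix; random mixes
with unknown ≤ 0.3; the 23%-air/77%-unknown design) from {0, 1, 2}.

This module is a functional stand-in for FEAST-style source tracking —
same mixture model and sink-side EM, without FEAST's joint multi-sink
variational machinery — and is documented as such. No rarefaction is
applied; depth enters through the multinomial likelihood.

## Co-occurrence networks

Genera are filtered by *mean* relative abundance > 1% across the
subject's inside-phase samples (the per-sample alternative is unstable
for edge filtering at n ≈ 8–18). All genus–genus, genus–cytokine and
cytokine–cytokine pairs are Spearman-correlated (average ranks,
t-approximation on n − 2 df); edges require |ρ| ≥ 0.5. Significance is
double-reported deliberately: the display convention flags raw
p ≤ 0.05, while BH-FDR q-values over all tested pairs are attached to
every edge — the two conventions coexist in practice and the package
reconciles them by reporting both. Constant series are skipped rather
than erroring the whole network.

## Pipeline

Stages run in dependency order (simulate → refnorm → trends → diversity
→ ordination → sourcetrack → network); each writes TSVs prefixed with a
comment line carrying the config hash and seed, and a stage report
records status and key counts. A stage failure aborts downstream stages;
disabling the tree skips the UniFrac analysis with a logged notice
rather than failing. Reruns with the same config are bitwise identical
(wall-clock timings are logged, never written to outputs). Problem sizes
throughout (200 OTUs, 72 samples, 100-replicate null calibrations,
20-replicate recovery checks) were chosen as the smallest at which the
statistical properties under test are stable.

## Known limitations

- The stationarity verdict is a descriptive operationalization
  ("≤ 5% of lags significant"), not a formal unit-root test.
- Source attribution inherits the identifiability limits of mixture
  models: unknown-pool mass resembling a source is credited to the
  source (slight systematic under-attribution of air in the
  dominant-unknown design, a few percentage points).
- Network inference at n = 8 inside-phase samples has low power and a
  non-trivial false-edge rate at |ρ| ≥ 0.5; the recovery guarantees in
  the tests are stated at n = 18.
- MANOVA p-values assume approximate multivariate normality of PC
  scores within groups; with 200-dimensional compositions reduced to
  ≤ 25 PCs this is adequate for the cohort sizes generated here but is
  not checked.
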