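# microdyn

Longitudinal analysis of microbial communities and immune markers in a
small, repeatedly-sampled cohort — the setting of enclosed-habitat crew
studies, where a handful of subjects are tracked before, during and
after a stay in a shared closed environment. The package asks, and
answers statistically:

- Is each subject's (salivary) microbiota **stationary** over months, or
  does it trend?
- Does a **shared living space make individuals' communities converge**?
- How much of the community is seeded from the **habitat air**?
- Which microbial genera **co-vary with salivary cytokines**
  (IL-1β, IL-6, IL-10, TNF-α, IFN-γ)?

Because raw sequencing data for such studies is rarely needed to develop
or validate the statistics, the package ships a seeded synthetic cohort
generator that reproduces the study design (subject-specific baseline
communities, a shared-environment component inside the habitat, air
sources, linked cytokines) with a full truth record, so every stage is
testable end to end.

## Methods at the core

**Reference-community normalization.** Per-sample fractional abundances
are compositional: a bloom of one taxon deflates every other taxon's
fraction. For each subject: (i) normalize each time point to sum 1;
(ii) select the highly abundant OTUs accounting for 90% of median
time-point reads; (iii) rescale each time point toward a reference
community computed from the *other* time points, weighted by community
similarity — weight $(1-j)^2$ where $j$ is the Jensen–Shannon distance
(base-2 logs, $j\in[0,1]$) between abundant-OTU subcompositions, with
reference OTU values the weighted medians across time points and the
rescaling factor the median reference/observed ratio.

**Stationarity and trend.** The sample autocorrelation function (biased
estimator, band $\pm 1.96/\sqrt{n}$) operationalizes the stationarity
assumption; the Mann–Kendall test,
$S=\sum_{i<j}\mathrm{sign}(x_j-x_i)$ with tie-corrected variance and
continuity correction, tests for monotone trends over the
outside-to-inside window.

**Convergence.** Weighted UniFrac
$d(P,Q)=\sum_b \ell_b\,|P_b-Q_b| \,/\, \sum_b \ell_b\,(P_b+Q_b)$
between subjects at matched time points, grouped by experimental phase
and compared by Kruskal–Wallis on per-time-point means (pooling all
pairs would pseudo-replicate; see `docs/methods.md`).

**Group separation.** PCA of OTU fractions; Mahalanobis distances
between group means on the first 25 PCs under the pooled covariance;
Wilks' Λ (Rao's F), pairwise Hotelling T² (Bonferroni), single-linkage
clustering of group means.

**Source tracking.** Each saliva sink is a multinomial mixture
$\sum_k \alpha_k\beta_k + \alpha_u\beta_u$ over air sources plus an
unknown pool, fitted by a two-stage EM that fixes the unknown
distribution at the noise-thresholded residual of a uniform-unknown fit
(a fully flexible unknown is degenerate — it can always absorb the
sources).

**Co-occurrence networks.** Genera above 1% mean relative abundance
inside the habitat, Spearman correlations with each other and the
cytokine panel, edges at $|\rho|\ge 0.5$, raw p-values flagged at 0.05
and Benjamini–Hochberg q-values reported alongside.

## Worked example

The numbered scripts under `analysis/` run the whole study on the
synthetic cohort (seed 0), writing tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/04_convergence.py
```

prints

```
cohort: 200 OTUs x 72 samples
subjects: ['A', 'B', 'C', 'D']
depth: min=16187, mean=34812
...
Kruskal-Wallis across phases: H=13.421, p=0.001218
  phase 1: median between-subject distance 0.428
  phase 2 (inside): median between-subject distance 0.267
  phase 3: median between-subject distance 0.447
inside-phase distances are the lowest -> shared environment reduces individual differences
```

Half of each inside-phase community is drawn from a shared pool in this
cohort, so between-subject weighted UniFrac distances drop from ~0.43
outside to ~0.27 inside and the phase effect is significant
(p ≈ 0.001) — then recover after the subjects "leave". The other
scripts report per-subject core-OTU counts (~85–100 of 200 OTUs),
mostly non-significant Mann–Kendall trends, subject/gender separation
at p < 0.001, near-zero air attribution for air-independent saliva
(vs ~21% when sinks truly contain 23% air), and recovery of all three
planted genus–cytokine links with correct signs.

The same pipeline runs from a single config:

```sh
microdyn run-all --config configs/demo.yaml        # or per-stage subcommands:
microdyn simulate --seed 0 --out results/cohort
microdyn refnorm --otu-table results/cohort/otu_table.tsv \
    --metadata results/cohort/metadata.tsv --subject A --out norm_A.tsv
```

Reruns with the same config and seed are bitwise identical.

## Layout

```
src/microdyn/       library: io, synthetic, refnorm, temporal,
                    diversity, ordination, sourcetrack, network,
                    pipeline, cli
analysis/           numbered narrative drivers (01_simulate ... 07_networks)
configs/demo.yaml   demo pipeline configuration
scripts/acceptance.py
tests/              pytest suite
docs/methods.md     model & design notes
```
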