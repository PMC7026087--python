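# Methods

This note documents the statistical machinery implemented in `stressnet`,
the assumptions behind it, and the design decisions taken where a choice
had to be made.  The package analyses factorial bulk RNA-seq designs in
which gonadal sex (F/M, set by gonad type) and genetic sex (XX/XY, set by
chromosome complement) vary independently — the four-core-genotypes (FCG)
cross — combined with a chronic-stress exposure and several brain
regions.

## Synthetic data generator

Because the analyses are validated on planted structure, the generator is
first-class, tested code.

**Count model.** Counts are negative-binomial:
`X_gs ~ NB(mu_gs, phi_g)` with `Var = mu + phi mu^2`.  The log2-scale mean
is additive,

```
log2 mu_gs = b_g + sex effects + stress effects + lambda_g(c_s) z_ms
```

with a per-gene baseline `b_g ~ U(4, 10)` (counts of roughly 16–1000,
typical for filtered bulk libraries), gene-wise dispersion
`phi_g ~ logU(0.05, 0.5)` spanning common bulk overdispersion, and
library-size factors `logU(0.7, 1.4)` multiplying the natural-scale mean.

**Planted sex effects** are attributable by construction: a
gonadal-attributed gene's shift depends only on the gonadal-sex column, a
genetic-attributed gene's only on XX/XY, and "both" genes carry one shift
of each kind with a common sign.  All planted contrasts are oriented
female/XX-high = positive so that direction-consistency in the
attribution step is plain sign equality.  Sex-effect genes are drawn
outside the planted modules so module-correlation checks are not
confounded by mean shifts.

**Planted stress effects** are (gene set, log2 shift, region, gonadal
sex) tuples applied to stressed samples only; a coherence plan (which
shared genes move in the same or opposite direction in a region pair) is
derived from them and recorded in the ground truth.

**Planted co-expression.** Module correlation comes from a per-module,
per-sample standard-normal latent factor added on the log2-mean scale.
With no separate idiosyncratic Gaussian term, the counting noise itself
plays the idiosyncratic role, so a loading

```
lambda_g = sqrt(rho / (1 - rho)) * sigma_g
```

gives every within-module pair expected log-expression correlation `rho`
exactly, where `sigma_g` is the gene's counting-noise standard deviation
on the log2 scale.  `sigma_g^2` is approximated by a gamma–Poisson
decomposition — trigamma(1/phi) for the mixing part plus an
`E[1/rate]` Poisson part inflated by the lognormal latent factor — and
the loading is solved by a short fixed-point iteration because the noise
grows with the loading itself.  Asymptotic checks (hundreds of samples)
reproduce requested correlations of 0.15–0.9 within ±0.02.  The latent
factor is standardized within each (stress, gonadal sex) cell so the
realized correlation matches the request even at the study's small group
sizes; without this, the shared-factor variance realized over ~6–18
samples dominates the error budget.

**What the generator does not emulate:** batch effects, GC/length bias,
sample swaps, pooling artifacts beyond the variance absorbed by the
dispersion, region-specific baselines, and mean–correlation coupling of
real co-expression.  Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated noise
model, not robustness to every failure mode of real data.

## Preprocessing

Genes are ranked by total count over all samples and the lowest
`floor(fraction * n_genes)` removed (default fraction 0.25).  Ties at the
boundary are resolved by gene identifier — the lexicographically later
gene is kept — purely for reproducibility.  Library sizes are column sums
*after* filtering, matching the stated processing order (filter, then
transform).  Expression is `log2((count + 0.5) / (libsize + 1) * 1e6)`,
and optional precision weights come from a lowess fit (span 0.5) of
sqrt(residual SD) against mean log2 count, evaluated per observation with
flat extrapolation and inverted as variance^-1.  The weights are optional
downstream; the default DE path is unweighted.  The qPCR helper maps a
delta-Ct (against the geometric mean of housekeeping genes) to the
arbitrary signal `2^-dCt * 10^4`.

## Differential expression and attribution

Per gene, the default test is Welch's two-sample t on log2 expression;
`moderated=True` shrinks the pooled gene-wise variances toward a common
prior with prior df and prior variance estimated by method of moments on
the observed variance distribution (a moderated-t in the limma family),
adding the prior df to the test's degrees of freedom.  The DE rule is raw
`p < 0.05` and linear fold change `> 1.3`, both strict; `q` (BH) is
reported alongside for transparency.  Fold change is `2^|mean_a - mean_b|`
on the log2-CPM scale, the only definition symmetric in direction under a
">1.3" threshold.

Attribution intersects the overall sex-DE set (XX females vs XY males)
with the gonadal-sex and genetic-sex DE sets; by default an overlap
counts only when the direction matches (XX-high aligned with
female-high).  All seven Venn regions are reported.

At n = 9 per group the raw-p rule retains roughly 5% of null genes, so
attribution percentages saturate only when planted effects dominate the
called set; this is a property of the rule, not of the implementation.

## RRHO coherence maps

Each DE result becomes a full ranking by the signed score
`-log10(p) * sign(log2FC)` (p floored at 1e-300; ties broken by gene id;
zero-effect genes score 0).  For every rank-threshold pair `(i, j)` on a
regular stride (default `max(1, N // 100)`, about a 100x100 grid), the
overlap `k = |top_i(A) ∩ top_j(B)|` is scored against
`Hypergeometric(N, i, j)`: cells at or above expectation store
`-log10 P(X >= k)` (positive), cells below store `log10 P(X <= k)`
(negative).  Tails are exact pmf sums accumulated in log space (segmented
logsumexp over gammaln terms), verified against independent brute-force
sums to ~1e-12 relative error on the p scale; without log-space
accumulation, cells at extreme thresholds underflow.

Quadrants are split at each list's sign-change rank.  The coherence call
follows the location of the global maximum |cell|: concordant quadrant →
coherent, discordant → anti-coherent, tie across both → mixed, maximum
below the significance threshold → none.  Only the global peak is
diagnostic because a strong concordant hotspot also produces weaker
secondary enrichment across quadrant boundaries (the complement of a
hotspot), and a strong anti-concordant signal appears as extreme
*depletion* (negative cells) in the discordant quadrants.  Grid-level
correction is available as Benjamini–Yekutieli over cells or a
max-statistic permutation family-wise null (≥20 permutations).

## Co-expression networks

Unsigned Pearson adjacency `|r|^beta` with default `beta = 6` (an
automatic chooser picks the smallest beta whose log-log degree
distribution fit reaches signed R² ≥ 0.8 over 10 connectivity bins).
Topological overlap follows the standard formula with connectivity sums
excluding the diagonal.  Modules come from average-linkage clustering of
`1 - TOM` with a *static* cut; clusters below 30 genes are unassigned
("grey") and surviving clusters get palette colours by decreasing size.

The static-cut height default is **0.95**.  At the sample sizes this
package targets (tens of samples), the dissimilarity of unrelated genes
plateaus just below 1.0, and a cut at 0.99 absorbs hundreds of noise
genes into real modules (planted-module recovery ARI drops from ~0.9 to
~0.6); 0.95 sits below that plateau while leaving genuine modules intact
and still sends all-noise data entirely to grey.  Dynamic tree cutting
was deliberately not used: the static cut is deterministic and sufficient
for planted-structure recovery.

**Preservation** uses a two-statistic permutation Z: density (mean
off-diagonal within-module adjacency in the test network) and
connectivity (correlation of intramodular connectivity vectors between
reference and test networks), each standardized against `n_perm` random
equal-size gene sets; `Z_summary` is their mean and `> 10` counts as
highly preserved.  A degenerate null (sd = 0, e.g. in self-preservation
where every random set has connectivity correlation 1) sets that Z to 0
with a warning.  For modules planted with uniform internal correlation
the connectivity statistic carries little signal (the intramodular
connectivity pattern is pure noise), so `Z_summary` is roughly half of
`Z_density`; hub-structured real modules would score higher.

## Module differential connectivity

For module genes G, connectivity is the sum of the strictly-lower
triangle of the adjacency over G; `MDC = connectivity(stress) /
connectivity(ctrl)` with adjacency computed independently per condition
on the same genes.  Two permutation nulls give two-sided p-values on
|log MDC| with the add-one estimator `(1 + #extreme) / (n_perm + 1)`:

- *shuffled samples*: condition labels permuted over the pooled samples
  and both adjacencies recomputed — real genes, randomized condition
  split; exchangeable under the null of no condition difference;
- *shuffled genes*: the module replaced by a uniform random equal-size
  gene set with the real condition split — random genes, real
  connectivity structure.

A third scheme, `shuffled_values` (pooling both conditions' lower
triangles and randomly reassigning values), is available behind a flag as
an alternative reading of "randomizing values across the lower triangular
matrix"; it is not the default because adjacency entries sharing samples
are strongly dependent, so value-level exchange does not hold and its
null can be anticonservative.

BH runs across modules within each scheme; a gained (MDC > 1) or lost
(MDC < 1) call requires `q < 0.05` under *both* schemes — a deliberately
conservative conjunction, since no combination rule is canonical.
Consequences worth knowing: at ~12–18 samples per condition and beta = 6,
losses from a well-correlated baseline are called with high power (the
stressed connectivity collapses to the noise floor), while gains are
capped — a control network correlated enough to pass preservation already
carries substantial `|r|^6` mass, limiting the achievable ratio — so
gain calls need larger planted shifts or more samples.  Measured power at
the package's validation sizes: ~85% for a 0.2→0.7 correlation gain
(30 genes, 12+12 samples, 1000 permutations) and ~70% for the joint
female-gain/male-loss pattern of a shared-control module (50 genes,
18+18 per sex).

## Hub networks

Per-condition networks use |Spearman rho| with either a fixed edge
threshold or a permutation-calibrated one (the (1-FDR) quantile of
pairwise scores after independently permuting every gene's samples).  A
mutual-information variant bins each gene into floor(sqrt(n)) equal-
frequency bins and prunes each fully connected triangle's weakest edge
when it is weaker than both others by more than 0.1 (the data-processing
inequality heuristic of relevance-network methods).

NHNN (N-hop neighborhood nodes) is the number of distinct nodes within N
unweighted hops (default N = 2; the criterion "significantly higher than
the average NHNN" is operationalized as z > 2 across nodes, with a
degree-preserving rewiring alternative behind a flag; sd = 0 yields no
hubs).  Stress-specific hubs are stressed-network hubs minus
control-network hubs.  Edge export keeps scores strictly above 0.95 by
default, canonically ordered.

## Pipeline

Stage order: preprocess → DE (attribution contrasts on non-stressed
samples, pooled over regions, plus per-region stress contrasts for XX
females and XY males) → RRHO per sex over region pairs → module
detection on all stressed samples with preservation against the
non-stressed network (only preserved modules continue, mirroring the
"only highly preserved modules analysed further" convention) → per-sex
MDC → per-sex, per-condition hub networks for modules with a
connectivity call.  A single global seed is fanned out to stages through
`SeedSequence(seed, spawn_key=(stage_index,))`, so reruns are
byte-identical and stages can be rerun in isolation.

The bundled demo generates ~2400 genes × 72 samples with gonadal-only,
genetic-only and shared sex effects, a female anti-coherent BLA/NAc pair,
a male coherent PFC/NAc pair, and five planted modules including one with
a sex-opposite connectivity change.  Demo correlations are chosen so each
planted pattern survives the detection → preservation → MDC cascade at
these sample sizes (pooled stressed correlation ≥ ~0.6 to be detected;
control correlation ≥ ~0.45 to be preserved).  Given the gain/loss power
asymmetry above, the sex-opposite module reliably shows a male loss call
and a female ratio > 1; the full joint called pattern appears in roughly
seven of ten seeds.

## Validation problem sizes

The test suite and the acceptance script run the statistical validations
at reduced but representative sizes chosen as a deliberate compromise
between statistical resolution and a test suite that runs in minutes:
10,000 genes for DE calibration; 2,000-gene universes for RRHO, module
recovery and MDC; 100–200 replicates for RRHO pattern recovery; 20
replicates at 1,000 permutations for MDC power runs.  All simulations
are seeded; the acceptance script derives every stream from its `--seed`
argument.

## Known limitations

- Adjacency and TOM are dense in-memory matrices; ~5k genes is a
  practical ceiling on a laptop-class machine.  Genome-scale runs would
  need block-wise computation.
- Only CPM/log normalization is implemented (no TMM or quantile); counts
  are assumed comparable after library-size scaling.
- The moderated test shrinks toward a single prior variance, not a
  mean-dependent trend.
- Preservation implements the two-statistic Z_summary, not the full
  multi-statistic battery of the reference method.
- The per-gene dispersion and baseline distributions are generic; no
  attempt is made to match any particular study's empirical moments.
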