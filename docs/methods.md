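# Methods

This note documents the models, conventions and numerical choices behind
`grpsig`, and what the synthetic experiments do and do not demonstrate.

## Biological meaning and hierarchy levels

The meaning measure is purely set-valued: M(gene) is the set of GO terms
directly annotated to the gene in one category, M(gene set) the union
over the set, and similarity of two sets is their meaning intersection —
zero similarity means an empty intersection. No information-content or
graph-distance semantic similarity is used; the disjointness certificate
of the GRP is exact set algebra, which is why it can be asserted on
every run at negligible cost.

Only `is_a` edges define the hierarchy. The level of a term is the
**shortest** `is_a` path to its category root (root = 0). Shortest-path
is deterministic, matches common GO-level usage, and is total on any
rooted DAG; a longest-path alternative is available
(`term_levels(..., mode="longest")`, `GrpConfig(level_mode=...)`). Each
term must reach exactly one category root; cycles, orphans and
cross-category `is_a` edges are structural errors, caught at
construction.

Annotations are taken as given (direct) by default.
`Annotation.propagate()` applies the true-path rule (copy each gene's
terms to all ancestors) for users whose annotation files are not
pre-propagated; it is off by default because the GRP semantics are
defined on whatever term sets the annotation supplies. Genes with no
annotation have meaning ∅: they can never violate disjointness and stay
eligible for sampling.

The GRP defaults to the biological-process category; `GrpConfig.category`
selects MF or CC instead. A run uses exactly one category.

## The removal schedule

The signature's terms R are processed by level, deepest (most specific)
first, cumulatively: the stage at level l removes the genes of all terms
with level ≥ l. Consequently pools shrink monotonically, the terminal
stage (l = L_min) has removed the genes of every term in R, and a
sentinel stage `ALL` produces that terminal pool directly. Random sets
are drawn fresh at each stage (not nested); each stage uses an
independent, deterministically derived RNG substream
(`SeedSequence([seed, stage_index])`), so adding or dropping stages
never perturbs the draws of other stages.

Stopping: the run ends at L_min, or earlier — before sampling — when the
pool falls below `min_pool_multiplier` (default 2) × |BM ∩ G|. The
matched size for sampling is |BM ∩ G|, the part of the signature present
in the cohort, which is also the size the stop rule uses.

Bonferroni correction uses m = `n_random_sets` (default 1000), the
number of hypothesis tests per stage. The stage summary reports the
median, the empirical 0.03-quantile (reported as "lower third
percentile", linear interpolation between order statistics) and the
fraction of raw p-values below α.

## Scoring: PC1 → median split → log-rank

PCA is computed on the samples × signature-genes submatrix with genes
mean-centered and (by default) not variance-scaled; scores are the
projections onto the leading right singular vector. The eigenvector sign
is fixed by making the largest-magnitude gene loading positive — runs
are bit-reproducible, and the choice is immaterial because the
downstream two-group test is invariant under a label flip. Ties at the
median PC1 score join group −1 (the below-median group); the rule is
arbitrary but declared and tested, making the split total and
deterministic. Degenerate inputs error out rather than guess: no
signature gene in the matrix, fewer than 3 samples, constant submatrix,
all-identical scores.

The two-group comparison is the Mantel–Haenszel log-rank statistic with
ties pooled at each distinct event time and hypergeometric variance;
subjects censored exactly at an event time are counted at risk at that
time. The statistic is implemented directly as a vectorized O−E/V
tabulation because the resampling analyses evaluate it ~10⁵–10⁶ times
per study and per-call overhead dominates otherwise; the test suite
checks it to 1e-12 against a from-scratch per-time tabulation, against
`lifelines`, and against an exhaustive permutation distribution on small
inputs. Kaplan–Meier curves are estimated via `lifelines`. p-values are
floored at the smallest positive normal float (with a `p_floored` flag)
so log₁₀ summaries stay finite; a zero log-rank variance with non-zero
O−E is an error, with the single exception O−E = 0, which yields
statistic 0 and p = 1 exactly.

## Expression conventions

FPKM follows 1e9 · reads / (protein-coding total · gene length);
FPKM-UQ replaces the total with the per-sample 75th percentile of
protein-coding gene counts, computed with the linear-interpolation
(type-7) quantile over all coding genes, zeros included — the quantile
convention is a declared choice, not given by the FPKM-UQ definition
itself. Gene filtering keeps protein-coding genes whose missing fraction
is strictly below the threshold (complete genes always pass, so a
threshold of 0 keeps exactly the genes without missing values).
Expression values enter PCA as-is; a `log2(x+1)` transform exists
(`CohortData.log2p1()`) but is off by default. Missing values are
filtered, never imputed.

## The synthetic model

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Ontology**: a balanced `is_a` tree per category (depth 3, branching
  2 → 15 terms by default), optionally with random cross-level edges
  that make shortest-path levels differ from tree depth.
* **Annotation**: each gene draws Poisson(2) terms uniformly from the
  non-root terms. An optional "module term" concentrates the planted
  module's genes on one term, for demonstrations where the GRP must
  strip the prognosis-carrying genes.
* **Cohort**: per-sample latent factor f ~ N(0,1); module genes read
  b·f + N(0, σ²) with b = σ = 1 (per-gene SNR 1), all other genes pure
  N(0, σ²) noise; survival time is the minimum of an exponential event
  time with rate λ₀·exp(β·f) (λ₀ = 1e-3/day, so a median event time of
  ~2 years at f = 0), an independent exponential censoring time
  (λ_c = 5e-4/day) and a 10-year administrative cutoff. These defaults
  give roughly 60% observed events, a realistic progression-endpoint
  regime for a ~500-patient tumor cohort. β may be 0, giving an exact
  null in which expression and outcome are independent.
* **Signatures**: the planted module plus 32 decoy sets drawn from
  non-module genes, with the acronyms and post-mapping sizes of the
  published prostate-cancer signature catalog (2 to 167 genes), so
  catalog-level analyses run at realistic set sizes.

The exponential/log-linear hazard is the simplest model under which the
PC1 → median-split → log-rank chain has analyzable power, and the
censoring is non-informative by construction, matching the log-rank
test's assumptions. The generator deliberately does **not** model
RNA-seq count distributions (negative binomial, library-size effects),
batch structure, correlated co-expression modules beyond the planted
one, or annotation realism (term sizes are roughly exchangeable rather
than power-law). Passing tests therefore demonstrate correctness of the
machinery and calibration/power under the stated model — not that any
real signature is or is not biologically meaningful.

## Problem sizes and seeds

The bundled experiments use 2000 genes × 400–498 samples, 1000 random
sets per stage, 200 replicates for power and 1000 sets for null
calibration — sizes at which every analysis completes in seconds while
keeping binomial/KS bands tight. Power and correlation thresholds
(≥ 95% detection, |corr(PC1, f)| > 0.9 at b/σ = 1, module 10, n = 400)
were fixed from a 50-replicate pilot run before being asserted. All
randomness flows from explicit integer seeds through
`numpy.random.Generator`; identical configuration and seed reproduce
results bit for bit, including across stage counts.

## Known limitations

* Meaning is binary set membership; partially overlapping but distinct
  terms (e.g. sibling terms) count as fully disjoint.
* The GRP treats the annotation as ground truth; incomplete annotation
  makes disjointness easier to achieve than it would be with propagated
  or richer annotations.
* Only two risk groups, a single PC, and the unweighted log-rank family
  are supported; no Cox adjustment for covariates.
* The FPKM routines expect a count table with gene lengths; they do not
  parse aligner or quantifier output formats.
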