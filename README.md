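# grpsig — surrogate gene sets for prognostic expression signatures

Published prognostic gene signatures (for prostate cancer in particular)
stratify patients into good- and bad-outcome groups remarkably well — but
does that mean the genes in them carry unique biological information about
the disease? `grpsig` implements the analysis that asks this question the
hard way: it constructs **random gene sets that provably share zero Gene
Ontology terms with a signature** and shows they can predict outcome just
as well. A random set that is significantly prognostic despite having no
biological meaning in common with the signature is a *surrogate gene set*.

## The method

**Biological meaning.** The meaning of a gene g is its GO-term set M(g)
within one category (biological process by default); the meaning of a gene
set is the union M({g₁,…,gₘ}) = M(g₁) ∪ … ∪ M(gₘ). Two gene sets are
biologically disjoint when M(A) ∩ M(B) = ∅.

**Gene Removal Procedure (GRP).** For a signature BM inside a cohort gene
universe G:

1. remove BM from G (optionally also a proliferation gene list PG);
2. map BM's genes to their terms and hierarchy levels,
   R = {(GO₁, L₁), …, (GO_t, L_t)} — levels are shortest `is_a` path to
   the category root;
3. iterating levels deepest-first and cumulatively, remove every gene
   annotated to a term in R at the current level or deeper;
4. at each stage draw 1000 size-matched random sets from the remaining
   pool and score each exactly like the signature itself; Bonferroni-
   correct the 1000 p-values; stop at L_min or when the pool drops below
   2 × |BM ∩ G|.

At the terminal stage every sampled set satisfies M(RGS) ∩ M(BM) = ∅ —
the package asserts this certificate on every run.

**Scoring a gene set.** Samples are projected onto the first principal
component of the set's expression submatrix (genes mean-centered, no
scaling), split into groups −1/+1 at the median PC1 score, and the two
Kaplan–Meier curves are compared with the Mantel–Haenszel (log-rank)
test. The chain is deterministic given cohort and gene set.

Everything runs on plain-text inputs (expression/clinical TSV, GMT
signatures, OBO or TSV ontology, two-column annotation TSV or GAF), and a
synthetic-data module generates complete bundles with known ground truth:
a latent per-sample factor f ~ N(0,1) drives a 10-gene module
(expression b·f + noise) and an exponential hazard λ₀·exp(β·f) with
independent censoring.

## Worked example

```sh
python analysis/01_simulate.py   # write results/bundle/ (2000 genes x 498 samples)
python analysis/05_grp.py        # run the GRP on the planted signature
```

prints (seed 0):

```
signature PLANTED (10 genes): own p = 7.94e-33 (significant)
  level 3: pool 1809, median p 0.514, lower third percentile 0.0413, significant fraction 0.040
  level 2: pool 1556, median p 0.465, lower third percentile 0.0309, significant fraction 0.057
  level 1: pool 1385, median p 0.506, lower third percentile 0.0237, significant fraction 0.059
terminal stage: 1000/1000 sets share zero GO terms with the signature; 59 of them are surrogate gene sets (raw p < 0.05)
stop reason: levels-exhausted
```

Reading: the planted module is overwhelmingly prognostic (p ≈ 8e-33, as
it should be — it drives the hazard). The random sets drawn from pools
that share **no** GO terms with it are centred on p ≈ 0.5 (median), yet
at every stage a few percent of them are significant — at the terminal,
certified-disjoint stage, 59 of 1000 sets are surrogates. Prognostic
power does not require sharing the signature's biology.

The other drivers: `02_overlap.py` computes the pairwise asymmetric
gene- and term-overlap matrices of the signature catalog,
`03_signature_power.py` measures detection power and PC1–latent-factor
correlation over 200 replicates, `04_null_calibration.py` verifies the
rejection rate is nominal on a β = 0 cohort. The same functionality is
scriptable via the `grpsig` CLI (`simulate`, `overlap`, `grp`
subcommands).

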