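"""The Gene Removal Procedure (GRP) and its resampling analysis.

Given a cohort gene universe G and a biomarker signature BM, the GRP
builds a sampling pool guaranteed to share no biological meaning with the
signature:

1. remove the signature's genes from G;
2. optionally remove a proliferation gene list PG (to rule out
   proliferation-driven prognostic signal);
3. map the signature's genes to their GO terms and each term's hierarchy
   level, R = {(GO_1, L_1), …, (GO_t, L_t)} — a gene can carry several
   terms, so t may exceed the signature size;
4. remove, level by level, every gene annotated to those terms.

Levels are processed deepest-first (most specific terms first) and
cumulatively: the stage at level l removes the genes of all signature
terms with level ≥ l. The final stage (l = L_min) has removed the genes
of *every* signature term, so any set sampled from it has an empty
meaning intersection with the signature — the disjointness certificate is
asserted on every run. A sentinel stage ``"ALL"`` requests that terminal
pool directly.

At each stage, ``n_random_sets`` size-matched gene sets are drawn
uniformly without replacement and scored by the same PC1 → median split →
log-rank chain as the signature itself; raw p-values are Bonferroni
corrected for the number of sets drawn. Iteration stops at L_min or as
soon as the pool falls below ``min_pool_multiplier`` × |BM ∩ G|.

A random set with a significant p-value despite the guaranteed zero
GO-term overlap is a *surrogate gene set*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from grpsig.catalog import Signature
from grpsig.errors import DegenerateInputError
from grpsig.expression import CohortData
from grpsig.ontology import (
    Annotation,
    Ontology,
    genes_of_terms,
    meaning,
    meaning_overlap,
    term_levels,
)
from grpsig.survival import outcome_association

logger = logging.getLogger(__name__)

#: Sentinel stage level: remove the genes of all signature terms at once.
ALL = "ALL"


@dataclass(frozen=True)
class GrpConfig:
    """Tunables of the Gene Removal Procedure.

    ``n_random_sets``: random sets per stage (1000 by default).
    ``alpha``: significance level for the surrogate count.
    ``category``: GO category defining "biological meaning" (BP default).
    ``remove_proliferation`` / ``proliferation_genes``: optional removal
    of a proliferation gene list from the pool.
    ``min_pool_multiplier``: stop when the pool is smaller than this
    multiple of the in-cohort signature size (2 by default).
    ``level_mode``: hierarchy-level convention ("shortest" or "longest").
    """

    n_random_sets: int = 1000
    alpha: float = 0.05
    category: str = "BP"
    remove_proliferation: bool = False
    proliferation_genes: frozenset[int] = frozenset()
    seed: int = 0
    min_pool_multiplier: float = 2.0
    level_mode: str = "shortest"

    def __post_init__(self) -> None:
        if self.n_random_sets < 1:
            raise ValueError("n_random_sets must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class TermLevelSet:
    """The signature's GO terms paired with their hierarchy levels."""

    levels: dict[str, int]          # term -> level

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.levels)

    @property
    def l_min(self) -> int:
        return min(self.levels.values())

    @property
    def l_max(self) -> int:
        return max(self.levels.values())

    def __len__(self) -> int:
        return len(self.levels)

    def terms_at_or_deeper(self, level) -> frozenset[str]:
        """Terms with hierarchy level ≥ ``level`` (all terms for ALL)."""
        if level == ALL:
            return self.terms
        return frozenset(t for t, l in self.levels.items() if l >= level)


@dataclass(frozen=True)
class GenePool:
    """An eligible sampling pool with the provenance of each removal."""

    genes: frozenset[int]
    removed_signature: frozenset[int]
    removed_proliferation: frozenset[int]
    removed_term_genes: frozenset[int]
    stage_level: int | str


class StageSummary(NamedTuple):
    median_p: float
    q03_p: float
    frac_significant: float


@dataclass
class GrpStage:
    """One removal stage: the pool and the scored random sets."""

    level: int | str
    pool_size: int
    p_raw: np.ndarray
    p_bonferroni: np.ndarray
    summary: StageSummary
    sets: list[frozenset[int]]


@dataclass
class GrpResult:
    """Full per-signature GRP outcome."""

    signature: str
    signature_p: float
    signature_significant: bool
    stages: list[GrpStage]
    stop_reason: str
    config: GrpConfig
    set_size: int

    def detail_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for k, (pr, pb) in enumerate(zip(stage.p_raw, stage.p_bonferroni)):
                rows.append(
                    {
                        "level": stage.level,
                        "pool_size": stage.pool_size,
                        "set_index": k,
                        "p_raw": pr,
                        "p_bonferroni": pb,
                    }
                )
        return pd.DataFrame(rows)

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": stage.level,
                "pool_size": stage.pool_size,
                "median_p": stage.summary.median_p,
                "lower_third_percentile_p": stage.summary.q03_p,
                "frac_significant": stage.summary.frac_significant,
                "signature_p": self.signature_p,
                "stop_reason": self.stop_reason,
            }
            for stage in self.stages
        ]
        return pd.DataFrame(rows)


def bm_term_levels(
    signature: Signature,
    annotation: Annotation,
    ontology: Ontology,
    category: str = "BP",
    mode: str = "shortest",
) -> TermLevelSet:
    """All GO terms of the signature's genes in one category, each paired
    with its hierarchy level. Empty if no signature gene is annotated."""
    m = meaning(signature.genes, annotation, category)
    if not m:
        logger.warning(
            "signature %s has no annotated gene in category %s; "
            "the GRP degenerates to simple signature exclusion",
            signature.name, category,
        )
        return TermLevelSet(levels={})
    levels = term_levels(ontology, mode=mode)
    return TermLevelSet(levels={t: levels[t] for t in m.terms})


def build_pool(
    universe: frozenset[int] | set[int],
    signature: Signature,
    config: GrpConfig,
    tls: TermLevelSet,
    annotation: Annotation,
    stage_level: int | str,
) -> GenePool:
    """Sampling pool at one stage: universe minus signature, minus the
    proliferation list if flagged, minus the genes of every signature
    term at level ≥ ``stage_level`` (all terms for the ALL sentinel)."""
    universe = frozenset(universe)
    removed_sig = universe & signature.genes
    removed_pg = (
        universe & config.proliferation_genes if config.remove_proliferation else frozenset()
    )
    stage_terms = tls.terms_at_or_deeper(stage_level)
    removed_terms = universe & genes_of_terms(stage_terms, annotation)
    pool = universe - removed_sig - removed_pg - removed_terms
    return GenePool(
        genes=pool,
        removed_signature=removed_sig,
        removed_proliferation=removed_pg,
        removed_term_genes=removed_terms,
        stage_level=stage_level,
    )


def sample_random_sets(
    pool: GenePool | Iterable[int],
    size: int,
    n: int,
    rng: np.random.Generator | int,
) -> list[frozenset[int]]:
    """Draw ``n`` uniform without-replacement gene sets of ``size`` from
    the pool; reproducible under a seed or Generator."""
    genes = np.array(sorted(pool.genes if isinstance(pool, GenePool) else pool))
    if len(genes) < size:
        raise DegenerateInputError(
            f"pool of {len(genes)} genes cannot yield sets of size {size}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return [frozenset(rng.choice(genes, size=size, replace=False).tolist()) for _ in range(n)]


def bonferroni(pvals, m: int) -> np.ndarray:
    """Bonferroni correction: p → min(1, m·p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return np.minimum(1.0, m * p)


def summarize(pvals, alpha: float = 0.05) -> StageSummary:
    """Median, empirical 0.03-quantile ("lower third percentile", linear
    interpolation), and the fraction of p-values below alpha."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    return StageSummary(
        median_p=float(np.median(p)),
        q03_p=float(np.quantile(p, 0.03)),
        frac_significant=float(np.mean(p < alpha)),
    )


def _stage_rng(seed: int, stage_index: int) -> np.random.Generator:
    # per-stage substream: adding stages never perturbs earlier stages
    return np.random.default_rng(np.random.SeedSequence([seed, stage_index]))


def assert_disjoint(
    random_sets: Iterable[frozenset[int]],
    signature: Signature,
    annotation: Annotation,
    category: str,
) -> None:
    """Disjointness certificate: every sampled set must share no meaning
    with the signature."""
    bm_meaning = meaning(signature.genes, annotation, category)
    for k, rgs in enumerate(random_sets):
        overlap = meaning_overlap(meaning(rgs, annotation, category), bm_meaning)
        if overlap:
            raise AssertionError(
                f"random set {k} shares {len(overlap)} term(s) with the signature"
            )


def run_grp(
    cohort: CohortData,
    signature: Signature,
    ontology: Ontology,
    annotation: Annotation,
    config: GrpConfig = GrpConfig(),
) -> GrpResult:
    """Run the full Gene Removal Procedure for one signature.

    Stages iterate hierarchy levels deepest-first from L_max down to
    L_min, cumulatively; the terminal stage guarantees zero meaning
    overlap between every sampled set and the signature (asserted).
    Stops early when the pool falls below
    ``min_pool_multiplier × |BM ∩ G|`` (stop reason ``pool-exhausted``).
    """
    universe = frozenset(cohort.expr.index)
    bm_in_cohort = signature.genes & universe
    if not bm_in_cohort:
        raise DegenerateInputError(
            f"signature {signature.name} has no gene in the cohort universe"
        )
    set_size = len(bm_in_cohort)
    sig_assoc = outcome_association(cohort, bm_in_cohort)

    tls = bm_term_levels(
        signature, annotation, ontology, category=config.category, mode=config.level_mode
    )
    if len(tls) == 0:
        schedule: list[int | str] = [ALL]
    else:
        schedule = sorted({l for l in tls.levels.values()}, reverse=True)

    stages: list[GrpStage] = []
    stop_reason = "levels-exhausted"
    for idx, level in enumerate(schedule):
        pool = build_pool(universe, signature, config, tls, annotation, level)
        if len(pool.genes) < config.min_pool_multiplier * set_size:
            stop_reason = "pool-exhausted"
            logger.info(
                "GRP %s: pool of %d genes below %.0f x %d at level %s; stopping",
                signature.name, len(pool.genes),
                config.min_pool_multiplier, set_size, level,
            )
            break
        rng = _stage_rng(config.seed, idx)
        sets = sample_random_sets(pool, set_size, config.n_random_sets, rng)
        p_raw = np.array(
            [outcome_association(cohort, s).p_value for s in sets]
        )
        p_bonf = bonferroni(p_raw, config.n_random_sets)
        stages.append(
            GrpStage(
                level=level,
                pool_size=len(pool.genes),
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                summary=summarize(p_raw, config.alpha),
                sets=sets,
            )
        )
        is_final = (level == ALL) or (len(tls) and level == tls.l_min)
        if is_final:
            assert_disjoint(sets, signature, annotation, config.category)
            break

    return GrpResult(
        signature=signature.name,
        signature_p=sig_assoc.p_value,
        signature_significant=sig_assoc.p_value < config.alpha,
        stages=stages,
        stop_reason=stop_reason,
        config=config,
        set_size=set_size,
    )
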