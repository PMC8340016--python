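"""Synthetic ontologies, annotations, cohorts and signature fixtures.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without any download:

* a leveled GO-like DAG per category (balanced ``is_a`` tree plus random
  cross-level edges that exercise shortest-path level logic);
* gene → term annotations with Poisson-distributed annotation counts;
* an expression cohort with one latent-factor-driven prognostic gene
  module: a per-sample factor f ~ N(0, 1) drives the module genes
  (expression = b·f + noise) and the hazard (exponential survival with
  rate λ0·exp(β·f)), with independent exponential censoring and an
  administrative cutoff. β = 0 gives an exact null cohort.
* signature fixtures: the planted module itself plus decoys whose sizes
  mirror the published prostate-cancer signature catalog (2–167 genes
  after Entrez mapping).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from grpsig.catalog import Signature, write_gmt
from grpsig.expression import CohortData, write_cohort
from grpsig.ontology import Annotation, Ontology

#: Study acronyms and post-mapping sizes of the 32 published
#: prostate-cancer prognostic signatures the decoy fixtures mirror.
PUBLISHED_SIGNATURE_SIZES: dict[str, int] = {
    "AGELL": 12, "BIBIKOVA": 16, "BISMAR": 12, "CHEN": 4, "CHEN_CC": 7,
    "CHEVILLE": 2, "CHU": 8, "CUZICK": 31, "GLINSKY": 11, "IRSHAD": 19,
    "IRSHAD_1": 3, "LARKIN": 7, "LI": 6, "LIU": 167, "LONG": 12,
    "NAKAGAWA": 17, "PENNEY": 157, "RAMASWAMY": 16, "REDDY": 16,
    "ROSS-ADAMS": 100, "ROSS": 6, "SAAL": 162, "SHARMA": 15, "SINGH": 5,
    "SONG": 15, "STEPHENSON": 10, "TALANTOV": 3, "TANDEFELT": 36,
    "TRUE": 86, "WANG": 43, "WU": 29, "YU": 14,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a prostate-cancer progression cohort: ~500 primary
    tumours, progression-free-interval-like follow-up with a baseline
    hazard of 1e-3/day (median event time ~2 years at f = 0),
    non-informative censoring at 5e-4/day, and a 10-year administrative
    cutoff. The prognostic module carries unit loading against unit
    noise (per-gene signal-to-noise 1).
    """

    n_genes: int = 2000
    n_samples: int = 498
    depth: int = 3
    branching: int = 2
    cross_edge_rate: float = 0.0
    annotation_density: float = 2.0
    module_size: int = 10
    loading_b: float = 1.0
    noise_sd: float = 1.0
    hazard_baseline: float = 1e-3       # per day
    log_hazard_beta: float = 1.0
    censoring_rate: float = 5e-4        # per day
    admin_cutoff_days: float = 3650.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_size > self.n_genes:
            raise ValueError("module_size cannot exceed n_genes")
        for name in ("n_genes", "n_samples", "depth", "branching",
                     "noise_sd", "hazard_baseline", "admin_cutoff_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def make_ontology(
    depth: int = 3,
    branching: int = 2,
    categories: tuple[str, ...] = ("BP", "MF", "CC"),
    cross_edge_rate: float = 0.0,
    seed: int = 0,
) -> Ontology:
    """Balanced ``is_a`` tree per category, optionally with extra
    cross-level edges (child → shallower term) at the given per-term
    rate, exercising shortest-path levels while staying acyclic."""
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    edges: list[tuple[str, str]] = []
    category: dict[str, str] = {}
    for cat in categories:
        counter = 0

        def tid(k: int) -> str:
            return f"{cat}:{k:04d}"

        root = tid(counter)
        category[root] = cat
        by_level: dict[int, list[str]] = {0: [root]}
        for lvl in range(1, depth + 1):
            by_level[lvl] = []
            for parent in by_level[lvl - 1]:
                for _ in range(branching):
                    counter += 1
                    child = tid(counter)
                    category[child] = cat
                    edges.append((child, parent))
                    by_level[lvl].append(child)
        if cross_edge_rate > 0:
            for lvl in range(2, depth + 1):
                for term in by_level[lvl]:
                    if rng.random() < cross_edge_rate:
                        target_lvl = int(rng.integers(0, lvl - 1))
                        target = by_level[target_lvl][
                            int(rng.integers(0, len(by_level[target_lvl])))
                        ]
                        edges.append((term, target))
    return Ontology.from_edges(edges, category)


def make_annotation(
    genes,
    ontology: Ontology,
    density: float = 2.0,
    seed: int = 0,
    module_genes=None,
    module_term: str | None = None,
) -> Annotation:
    """Annotate each gene to Poisson(density) uniformly chosen non-root
    terms (possibly zero). When ``module_term`` is given, the module
    genes are additionally all annotated to that term, so removing the
    term's genes demonstrably strips the prognosis-correlated module."""
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    roots = set(ontology.roots.values())
    candidates = np.array(sorted(ontology.terms - roots))
    gene_terms: dict[int, frozenset[str]] = {}
    for g in sorted(genes):
        k = rng.poisson(density)
        terms = set(rng.choice(candidates, size=min(k, len(candidates)), replace=False).tolist()) if k else set()
        if module_term is not None and module_genes is not None and g in set(module_genes):
            terms.add(module_term)
        if terms:
            gene_terms[int(g)] = frozenset(terms)
    return Annotation(gene_terms=gene_terms, ontology=ontology)


def make_cohort(config: SyntheticConfig, seed: int | None = None) -> tuple[CohortData, dict]:
    """Latent-factor cohort with exponential survival.

    Module genes (IDs 1 … module_size) read b·f_s + N(0, noise_sd²);
    every other gene is pure noise. Survival time is the minimum of an
    exponential event time with rate λ0·exp(β·f_s), an independent
    exponential censoring time (rate λc), and the administrative cutoff;
    the event indicator is 1 iff the event time attains the minimum.
    Returns the cohort and a ground-truth record (module genes, latent
    factor, true parameters).
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n, p, m = config.n_samples, config.n_genes, config.module_size
    f = rng.standard_normal(n)
    X = rng.normal(0.0, config.noise_sd, size=(p, n))
    X[:m] += config.loading_b * f[None, :]
    genes = np.arange(1, p + 1)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    rate = config.hazard_baseline * np.exp(config.log_hazard_beta * f)
    t_event = rng.exponential(1.0 / rate)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_cutoff_days)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    expr = pd.DataFrame(X, index=genes, columns=samples)
    cohort = CohortData(
        expr=expr,
        time=pd.Series(time, index=expr.columns, name="time"),
        event=pd.Series(event, index=expr.columns, name="event"),
    )
    truth = {
        "module_genes": [int(g) for g in genes[:m]],
        "latent_factor": f.tolist(),
        "beta": config.log_hazard_beta,
        "loading_b": config.loading_b,
        "noise_sd": config.noise_sd,
        "hazard_baseline": config.hazard_baseline,
        "censoring_rate": config.censoring_rate,
        "admin_cutoff_days": config.admin_cutoff_days,
        "seed": int(seed),
    }
    return cohort, truth


def make_signature_fixtures(
    config: SyntheticConfig,
    seed: int | None = None,
    decoy_sizes: dict[str, int] | None = None,
) -> list[Signature]:
    """The planted module as signature ``PLANTED`` plus decoy signatures
    drawn from non-module genes, sized like the published catalog."""
    if seed is None:
        seed = config.seed
    if decoy_sizes is None:
        decoy_sizes = PUBLISHED_SIGNATURE_SIZES
    rng = np.random.default_rng(seed)
    module = frozenset(range(1, config.module_size + 1))
    non_module = np.arange(config.module_size + 1, config.n_genes + 1)
    out = [Signature(name="PLANTED", genes=module, source="synthetic-module")]
    for name, size in decoy_sizes.items():
        if size > len(non_module):
            raise ValueError(f"decoy {name} of size {size} exceeds the non-module pool")
        genes = frozenset(rng.choice(non_module, size=size, replace=False).tolist())
        out.append(Signature(name=name, genes=genes, source="synthetic-decoy"))
    return out


def write_bundle(out_dir: str | Path, config: SyntheticConfig, seed: int | None = None) -> dict:
    """Write a complete synthetic input bundle (ontology, annotation,
    signatures, expression, clinical, ground truth) in the same formats
    the pipeline reads. Returns the ground-truth record."""
    if seed is None:
        seed = config.seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology = make_ontology(
        depth=config.depth, branching=config.branching,
        cross_edge_rate=config.cross_edge_rate, seed=seed,
    )
    cohort, truth = make_cohort(config, seed)
    annotation = make_annotation(
        sorted(cohort.genes), ontology, density=config.annotation_density, seed=seed
    )
    signatures = make_signature_fixtures(config, seed)
    ontology.to_obo(str(out / "ontology.obo"))
    ontology.to_tsv(str(out / "ontology.tsv"))
    annotation.to_tsv(str(out / "annotation.tsv"))
    write_gmt(signatures, str(out / "signatures.gmt"))
    write_cohort(cohort, str(out / "expression.tsv"), str(out / "clinical.tsv"))
    truth["config"] = asdict(config)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
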