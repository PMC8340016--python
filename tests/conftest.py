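"""Shared fixtures: toy ontologies, annotations, and small synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

from grpsig.catalog import Signature
from grpsig.expression import CohortData
from grpsig.ontology import Annotation, Ontology
from grpsig.synthetic import SyntheticConfig, make_cohort


@pytest.fixture
def chain_ontology() -> Ontology:
    """R <- B <- C, a single BP chain."""
    return Ontology.from_edges(
        [("C", "B"), ("B", "R")], {"R": "BP", "B": "BP", "C": "BP"}
    )


@pytest.fixture
def diamond_ontology() -> Ontology:
    """A is_a R; B is_a A; C is_a B and C is_a R (shortcut to the root)."""
    return Ontology.from_edges(
        [("A", "R"), ("B", "A"), ("C", "B"), ("C", "R")],
        {"R": "BP", "A": "BP", "B": "BP", "C": "BP"},
    )


@pytest.fixture
def toy_ontology() -> Ontology:
    """Two categories with a couple of terms each."""
    edges = [
        ("GO1", "BP_ROOT"), ("GO2", "BP_ROOT"), ("GO3", "GO1"), ("GO4", "GO2"),
        ("MF1", "MF_ROOT"), ("MF2", "MF_ROOT"),
    ]
    cats = {
        "BP_ROOT": "BP", "GO1": "BP", "GO2": "BP", "GO3": "BP", "GO4": "BP",
        "MF_ROOT": "MF", "MF1": "MF", "MF2": "MF",
    }
    return Ontology.from_edges(edges, cats)


@pytest.fixture
def toy_annotation(toy_ontology) -> Annotation:
    return Annotation(
        {
            1: frozenset({"GO1", "GO2"}),
            2: frozenset({"GO2", "GO3"}),
            3: frozenset({"MF1"}),
            5: frozenset({"GO1"}),
            9: frozenset({"GO1", "MF2"}),
        },
        toy_ontology,
    )


@pytest.fixture(scope="session")
def small_cohort_with_truth():
    """A 200-gene, 120-sample cohort with a planted 8-gene module."""
    cfg = SyntheticConfig(
        n_genes=200, n_samples=120, module_size=8, seed=11,
    )
    return make_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cohort_with_truth) -> CohortData:
    return small_cohort_with_truth[0]


@pytest.fixture
def tiny_cohort() -> CohortData:
    """Deterministic 4-gene, 6-sample cohort for hand-checkable cases."""
    rng = np.random.default_rng(3)
    samples = [f"P{i}" for i in range(6)]
    expr = pd.DataFrame(
        rng.normal(size=(4, 6)), index=[1, 2, 3, 4], columns=samples
    )
    return CohortData(
        expr=expr,
        time=pd.Series([5.0, 8.0, 3.0, 12.0, 7.0, 10.0], index=samples),
        event=pd.Series([1, 0, 1, 1, 1, 0], index=samples),
    )


@pytest.fixture
def planted_signature() -> Signature:
    return Signature(name="PLANTED", genes=frozenset(range(1, 9)), source="module")
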