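"""GO-like ontology: term DAG, hierarchy levels, and "biological meaning".

The biological meaning of a gene is the set of ontology terms annotated to
it within one category (biological process, molecular function, or cellular
component); the meaning of a gene *set* is the union over its genes. Two
gene sets are biologically disjoint when their meanings do not intersect —
this set-level definition is the disjointness certificate the Gene Removal
Procedure (:mod:`grpsig.grp`) guarantees for its random gene sets.

Only ``is_a`` edges define the hierarchy; ``part_of`` and other relations
are ignored, because hierarchy levels are only meaningful within a single
rooted DAG per category. The *level* of a term is the shortest ``is_a``
path to its category root (root = level 0); a longest-path convention is
available via ``mode="longest"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from grpsig.errors import CategoryMismatchError, DataValidationError, OntologyStructureError

logger = logging.getLogger(__name__)

#: Recognised GO categories.
CATEGORIES = ("BP", "MF", "CC")

_NAMESPACE_TO_CATEGORY = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
_CATEGORY_TO_NAMESPACE = {v: k for k, v in _NAMESPACE_TO_CATEGORY.items()}


@dataclass(frozen=True)
class Ontology:
    """A rooted, acyclic ``is_a`` hierarchy with one root per category.

    Parameters
    ----------
    graph
        Directed graph with edges child → parent (``is_a`` only).
    category
        Mapping term ID → category code (``BP``/``MF``/``CC``).
    roots
        Mapping category code → root term ID.
    """

    graph: nx.DiGraph
    category: Mapping[str, str]
    roots: Mapping[str, str]

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            raise OntologyStructureError("is_a graph contains a cycle")
        root_set = set(self.roots.values())
        for term in self.graph.nodes:
            if term not in self.category:
                raise OntologyStructureError(f"term {term!r} has no category")
            if term in root_set:
                continue
            parents = list(self.graph.successors(term))
            if not parents:
                raise OntologyStructureError(f"non-root term {term!r} has no parent")
            for p in parents:
                if self.category.get(p) != self.category[term]:
                    raise OntologyStructureError(
                        f"edge {term!r} -> {p!r} crosses categories; a term must "
                        "reach exactly one category root"
                    )

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def terms_in_category(self, category: str) -> frozenset[str]:
        return frozenset(t for t in self.graph.nodes if self.category[t] == category)

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` by following is_a edges upward."""
        return frozenset(nx.descendants(self.graph, term))

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        category: Mapping[str, str],
    ) -> "Ontology":
        """Build from (child, parent) pairs and a term → category map."""
        g = nx.DiGraph()
        g.add_nodes_from(category)
        g.add_edges_from(edges)
        roots: dict[str, str] = {}
        for term in g.nodes:
            if g.out_degree(term) == 0:
                cat = category.get(term)
                if cat is None:
                    raise OntologyStructureError(f"root candidate {term!r} has no category")
                if cat in roots:
                    raise OntologyStructureError(
                        f"category {cat} has two roots: {roots[cat]!r} and {term!r}"
                    )
                roots[cat] = term
        return cls(graph=g, category=dict(category), roots=roots)

    @classmethod
    def from_obo(cls, path: str) -> "Ontology":
        """Read an OBO file, keeping only ``is_a`` edges and the namespace."""
        multigraph = obonet.read_obo(path)
        category: dict[str, str] = {}
        edges: list[tuple[str, str]] = []
        for term, data in multigraph.nodes(data=True):
            ns = data.get("namespace")
            if ns not in _NAMESPACE_TO_CATEGORY:
                raise OntologyStructureError(f"term {term!r} has unknown namespace {ns!r}")
            category[term] = _NAMESPACE_TO_CATEGORY[ns]
        for child, parent, rel in multigraph.edges(keys=True):
            if rel == "is_a":
                edges.append((child, parent))
        return cls.from_edges(edges, category)

    @classmethod
    def from_tsv(cls, path: str) -> "Ontology":
        """Read the 3-column dialect ``child <tab> parent <tab> category``.

        Roots appear only in the parent column; their category is inferred
        from their children's rows.
        """
        edges: list[tuple[str, str]] = []
        category: dict[str, str] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise DataValidationError(f"{path}:{ln}: expected 3 columns")
                child, parent, cat = parts
                if cat not in CATEGORIES:
                    raise DataValidationError(f"{path}:{ln}: unknown category {cat!r}")
                edges.append((child, parent))
                category[child] = cat
                category.setdefault(parent, cat)
        return cls.from_edges(edges, category)

    def to_obo(self, path: str) -> None:
        """Write a minimal OBO serialization (id, namespace, is_a)."""
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\n")
            for term in sorted(self.graph.nodes):
                fh.write("\n[Term]\n")
                fh.write(f"id: {term}\n")
                fh.write(f"name: {term}\n")
                fh.write(f"namespace: {_CATEGORY_TO_NAMESPACE[self.category[term]]}\n")
                for parent in sorted(self.graph.successors(term)):
                    fh.write(f"is_a: {parent}\n")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for child, parent in sorted(self.graph.edges):
                fh.write(f"{child}\t{parent}\t{self.category[child]}\n")


def term_levels(ontology: Ontology, mode: str = "shortest") -> dict[str, int]:
    """Hierarchy level of every term: path length to its category root.

    ``mode="shortest"`` (default) uses the shortest ``is_a`` path, the
    common GO-level convention; ``mode="longest"`` uses the longest path.
    The root of each category has level 0. Total and deterministic.
    """
    if mode not in ("shortest", "longest"):
        raise ValueError(f"mode must be 'shortest' or 'longest', got {mode!r}")
    down = ontology.graph.reverse(copy=False)  # parent -> child
    levels: dict[str, int] = {}
    if mode == "shortest":
        for root in ontology.roots.values():
            for term, dist in nx.single_source_shortest_path_length(down, root).items():
                levels[term] = dist
    else:
        for root in ontology.roots.values():
            levels[root] = 0
        for term in nx.topological_sort(ontology.graph.reverse(copy=True)):
            for child in down.successors(term):
                if term in levels:
                    levels[child] = max(levels.get(child, 0), levels[term] + 1)
    missing = set(ontology.graph.nodes) - set(levels)
    if missing:
        raise OntologyStructureError(
            f"{len(missing)} term(s) unreachable from any category root, "
            f"e.g. {sorted(missing)[:3]}"
        )
    return levels


@dataclass(frozen=True)
class MeaningSet:
    """The biological meaning of a gene set: its GO terms in one category."""

    terms: frozenset[str]
    category: str

    def __len__(self) -> int:
        return len(self.terms)

    def __bool__(self) -> bool:
        return bool(self.terms)


@dataclass
class Annotation:
    """Gene → GO-term mapping attached to an :class:`Ontology`.

    Gene IDs follow the Entrez convention (positive integers). All term
    IDs must exist in the attached ontology. By default annotations are
    taken as given (direct); :meth:`propagate` returns a copy where every
    gene is also annotated to all ancestors of its terms (true-path rule).
    """

    gene_terms: dict[int, frozenset[str]]
    ontology: Ontology
    _inverse: dict[str, frozenset[int]] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        known = self.ontology.terms
        for gene, terms in self.gene_terms.items():
            if not (isinstance(gene, (int,)) and gene > 0):
                raise DataValidationError(f"gene ID {gene!r} is not a positive integer")
            unknown = terms - known
            if unknown:
                raise DataValidationError(
                    f"gene {gene}: unknown term(s) {sorted(unknown)[:3]}"
                )

    def terms_of(self, gene: int) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(self.gene_terms)

    def inverse(self) -> dict[str, frozenset[int]]:
        """Term → genes annotated to it (cached)."""
        if self._inverse is None:
            inv: dict[str, set[int]] = {}
            for gene, terms in self.gene_terms.items():
                for t in terms:
                    inv.setdefault(t, set()).add(gene)
            self._inverse = {t: frozenset(g) for t, g in inv.items()}
        return self._inverse

    def propagate(self) -> "Annotation":
        """Copy annotations to all ancestor terms (true-path rule)."""
        new = {
            gene: frozenset(
                set(terms).union(*(self.ontology.ancestors(t) for t in terms))
            )
            if terms
            else terms
            for gene, terms in self.gene_terms.items()
        }
        return Annotation(gene_terms=new, ontology=self.ontology)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_tsv(cls, path: str, ontology: Ontology) -> "Annotation":
        """Read 2-column TSV: gene ID, term ID; one pair per line."""
        pairs: dict[int, set[str]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise DataValidationError(f"{path}:{ln}: expected 2 columns")
                try:
                    gene = int(parts[0])
                except ValueError as exc:
                    raise DataValidationError(f"{path}:{ln}: bad gene ID {parts[0]!r}") from exc
                pairs.setdefault(gene, set()).add(parts[1])
        return cls({g: frozenset(t) for g, t in pairs.items()}, ontology)

    @classmethod
    def from_gaf(cls, path: str, ontology: Ontology) -> "Annotation":
        """Read GAF 2.x, consuming only the object-ID and GO-ID columns."""
        pairs: dict[int, set[str]] = {}
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("!"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 5:
                    raise DataValidationError(f"{path}:{ln}: fewer than 5 GAF columns")
                try:
                    gene = int(cols[1])
                except ValueError as exc:
                    raise DataValidationError(
                        f"{path}:{ln}: object ID {cols[1]!r} is not an Entrez integer"
                    ) from exc
                pairs.setdefault(gene, set()).add(cols[4])
        return cls({g: frozenset(t) for g, t in pairs.items()}, ontology)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for gene in sorted(self.gene_terms):
                for term in sorted(self.gene_terms[gene]):
                    fh.write(f"{gene}\t{term}\n")


def meaning(genes: Iterable[int], annotation: Annotation, category: str) -> MeaningSet:
    """Biological meaning of a gene set: union of per-gene term sets,
    restricted to one category.

    Genes absent from the annotation contribute nothing (their meaning is
    the empty set); they are counted and logged at debug level.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    cat = annotation.ontology.category
    out: set[str] = set()
    n_unknown = 0
    for g in genes:
        terms = annotation.gene_terms.get(g)
        if terms is None:
            n_unknown += 1
            continue
        out.update(t for t in terms if cat[t] == category)
    if n_unknown:
        logger.debug("meaning: %d gene(s) without annotation contributed nothing", n_unknown)
    return MeaningSet(terms=frozenset(out), category=category)


def meaning_overlap(a: MeaningSet, b: MeaningSet) -> MeaningSet:
    """Intersection of two meaning sets; empty ⇔ zero biological similarity."""
    if a.category != b.category:
        raise CategoryMismatchError(
            f"cannot intersect meanings from categories {a.category} and {b.category}"
        )
    return MeaningSet(terms=a.terms & b.terms, category=a.category)


def genes_of_terms(terms: Iterable[str], annotation: Annotation) -> frozenset[int]:
    """Union of the gene sets annotated to each term (inverse mapping)."""
    inv = annotation.inverse()
    out: set[int] = set()
    for t in terms:
        out.update(inv.get(t, frozenset()))
    return frozenset(out)
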