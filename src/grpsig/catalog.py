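"""Signature catalog: GMT I/O, symbol mapping, pairwise overlap statistics.

A *signature* is a published prognostic gene set identified by a study
acronym, with genes under the Entrez-ID convention (symbols without an
Entrez ID are discarded at mapping time).

The pairwise overlap of two signatures S_i, S_j is deliberately
*asymmetric*: the shared-element set x = S_i ∩ S_j is normalised by each
signature's own size, z_i = |x| / |S_i| and z_j = |x| / |S_j|, so a small
signature fully contained in a large one has z = 1 from its own point of
view. The same measure applies to the signatures' GO-term meaning sets
("terms" mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from grpsig.errors import DataValidationError, DegenerateInputError
from grpsig.ontology import Annotation, meaning

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signature:
    """A named gene set (Entrez IDs)."""

    name: str
    genes: frozenset[int]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise DataValidationError(f"signature {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class OverlapResult:
    """Asymmetric overlap of a signature pair."""

    shared: frozenset
    z_i: float
    z_j: float
    mode: str


def read_gmt(path: str) -> list[Signature]:
    """Read signatures from a GMT file (name, source, then gene IDs).

    Duplicate IDs within a line are deduplicated with a logged warning; a
    line with no genes is rejected with its line number.
    """
    out: list[Signature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataValidationError(f"{path}:{ln}: GMT line has no genes")
            name, source, raw = parts[0], parts[1], parts[2:]
            try:
                ids = [int(x) for x in raw if x]
            except ValueError as exc:
                raise DataValidationError(f"{path}:{ln}: non-integer gene ID") from exc
            if not ids:
                raise DataValidationError(f"{path}:{ln}: GMT line has no genes")
            genes = frozenset(ids)
            if len(genes) < len(ids):
                logger.warning(
                    "%s:%d: %d duplicate gene ID(s) in %s deduplicated",
                    path, ln, len(ids) - len(genes), name,
                )
            out.append(Signature(name=name, genes=genes, source=source))
    return out


def write_gmt(signatures: Iterable[Signature], path: str) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            genes = "\t".join(str(g) for g in sorted(sig.genes))
            fh.write(f"{sig.name}\t{sig.source}\t{genes}\n")


def map_symbols(
    symbols: Sequence[str], mapping: Mapping[str, int]
) -> tuple[frozenset[int], list[str]]:
    """Map gene symbols to Entrez IDs, discarding unmapped symbols.

    Returns the mapped ID set and the list of dropped symbols (input
    order). Many-to-one collisions collapse under set semantics.
    """
    mapped: set[int] = set()
    dropped: list[str] = []
    for s in symbols:
        if s in mapping:
            mapped.add(mapping[s])
        else:
            dropped.append(s)
    return frozenset(mapped), dropped


def _elements(sig: Signature, mode: str, annotation: Annotation | None, category: str):
    if mode == "genes":
        return sig.genes
    if mode == "terms":
        if annotation is None:
            raise ValueError("terms mode requires an annotation")
        return meaning(sig.genes, annotation, category).terms
    raise ValueError(f"mode must be 'genes' or 'terms', got {mode!r}")


def pairwise_overlap(
    si: Signature,
    sj: Signature,
    mode: str = "genes",
    annotation: Annotation | None = None,
    category: str = "BP",
) -> OverlapResult:
    """Asymmetric overlap z_i = |S_i ∩ S_j| / |S_i|, z_j likewise.

    In "terms" mode the compared elements are the signatures' meaning
    sets; a signature whose meaning is empty gets z = 0 (nothing can be
    shared).
    """
    ei = _elements(si, mode, annotation, category)
    ej = _elements(sj, mode, annotation, category)
    shared = frozenset(ei) & frozenset(ej)
    z_i = len(shared) / len(ei) if ei else 0.0
    z_j = len(shared) / len(ej) if ej else 0.0
    return OverlapResult(shared=shared, z_i=z_i, z_j=z_j, mode=mode)


def overlap_matrix(
    signatures: Sequence[Signature],
    mode: str = "genes",
    annotation: Annotation | None = None,
    category: str = "BP",
) -> tuple[pd.DataFrame, pd.Series]:
    """All-pairs overlap matrix plus per-signature non-zero partner counts.

    Entry (i, j) is z_i of signature i against signature j (normalised by
    row); the diagonal is 1. The partner count for a signature is the
    number of *other* signatures with a non-zero overlap against it.
    """
    if len(signatures) < 2:
        raise DegenerateInputError("overlap matrix needs at least 2 signatures")
    names = [s.name for s in signatures]
    if len(set(names)) != len(names):
        raise DataValidationError("duplicate signature names")
    elems = [frozenset(_elements(s, mode, annotation, category)) for s in signatures]
    n = len(signatures)
    z = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = elems[i] & elems[j]
            z[i, j] = len(shared) / len(elems[i]) if elems[i] else 0.0
    mat = pd.DataFrame(z, index=names, columns=names)
    off = mat.values.copy()
    np.fill_diagonal(off, 0.0)
    partners = pd.Series((off > 0).sum(axis=1), index=names, name="n_nonzero_partners")
    return mat, partners


def partner_fraction_pct(n_partners: int, n_other: int) -> float:
    """Share of partner signatures as a percentage, to one decimal place."""
    return round(100.0 * n_partners / n_other, 1)


def go_term_counts(
    signature: Signature, annotation: Annotation
) -> dict[str, int]:
    """Number of distinct GO terms of the signature's genes, per category."""
    return {
        cat: len(meaning(signature.genes, annotation, cat))
        for cat in ("BP", "MF", "CC")
    }
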