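"""PC1 patient stratification: score samples on the first principal
component of a signature's expression submatrix and split at the median.

Samples are the observations and the signature's genes the variables;
genes are mean-centered but not variance-scaled (a ``scale`` switch
exists). The PC1 score of a sample is its projection onto the leading
eigenvector of the gene–gene covariance. Samples at or below the median
score form group −1, samples above it group +1; the tie rule (ties at the
median join −1) makes the split total and deterministic. The eigenvector
sign is fixed by making the largest-magnitude gene loading positive —
harmless, since the downstream two-group survival comparison is invariant
under a label flip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from grpsig.errors import DegenerateInputError
from grpsig.expression import CohortData

logger = logging.getLogger(__name__)


@dataclass
class StratifiedGroups:
    """Two-group split of a cohort with the PC1 scores that induced it."""

    labels: pd.Series          # -1 / +1 per sample
    scores: pd.Series
    signature_name: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"score": self.scores, "group": self.labels})


def pc1_scores(
    cohort: CohortData, genes: Iterable[int], scale: bool = False
) -> pd.Series:
    """Per-sample score on the first principal component of the signature
    submatrix.

    Signature genes absent from the matrix are dropped with a logged
    warning; zero present genes, fewer than 3 samples, or a constant
    submatrix (no principal direction) are errors.
    """
    genes = set(genes)
    present = [g for g in cohort.expr.index if g in genes]
    if not present:
        raise DegenerateInputError("no signature gene present in the expression matrix")
    if len(present) < len(genes):
        logger.warning(
            "pc1_scores: %d signature gene(s) absent from the matrix dropped",
            len(genes) - len(present),
        )
    if cohort.n_samples < 3:
        raise DegenerateInputError("PC1 scoring needs at least 3 samples")
    X = cohort.expr.loc[present].to_numpy(dtype=float).T   # samples x genes
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise DegenerateInputError("constant expression submatrix: PC1 undefined")
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise DegenerateInputError("zero-variance gene under scaling")
        Xc = Xc / sd
    # leading right singular vector of the centered samples x genes matrix
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:   # deterministic sign
        v = -v
    return pd.Series(Xc @ v, index=cohort.expr.columns, name="pc1")


def median_split(scores: pd.Series, signature_name: str | None = None) -> StratifiedGroups:
    """Split samples at the median PC1 score: ≤ median → −1, > median → +1."""
    if len(scores) < 2:
        raise DegenerateInputError("median split needs at least 2 samples")
    if scores.nunique() == 1:
        raise DegenerateInputError("all scores identical: median split undefined")
    med = float(np.median(scores.values))
    labels = pd.Series(np.where(scores.values > med, 1, -1), index=scores.index, name="group")
    return StratifiedGroups(labels=labels, scores=scores, signature_name=signature_name)
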