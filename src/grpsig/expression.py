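"""Expression matrices, FPKM / FPKM-UQ normalisation, and gene filtering.

A cohort couples a genes × samples expression matrix (Entrez gene rows)
with per-sample survival follow-up: time in days and an event indicator
(1 = progression observed, 0 = censored).

FPKM (fragments per kilobase of transcript per million mapped reads) of a
gene g in sample s is

    FPKM(g, s) = 1e9 · reads(g, s) / (N_s · length(g))

where N_s is the total read count over protein-coding genes in sample s
and length(g) the gene length in base pairs. FPKM-UQ replaces N_s by the
sample's 75th-percentile protein-coding gene count (linear-interpolation
quantile, zeros included), which typically inflates the values since the
upper-quartile count is far below the total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from grpsig.errors import DataValidationError, DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass
class CohortData:
    """Expression matrix aligned with survival follow-up.

    ``expr``: DataFrame, rows = Entrez gene IDs, columns = sample IDs;
    NaN encodes missingness. ``time``/``event``: Series indexed by the
    same sample IDs, time in days (≥ 0), event in {0, 1}.
    """

    expr: pd.DataFrame
    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        if self.expr.index.duplicated().any():
            dup = self.expr.index[self.expr.index.duplicated()][0]
            raise DataValidationError(f"duplicate gene row {dup!r}")
        if self.expr.columns.duplicated().any():
            raise DataValidationError("duplicate sample columns")
        if not (self.time.index.equals(self.expr.columns)
                and self.event.index.equals(self.expr.columns)):
            raise DataValidationError("survival rows do not align 1:1 with matrix columns")
        if (self.time < 0).any():
            raise DataValidationError("negative survival time")
        if not self.event.isin([0, 1]).all():
            raise DataValidationError("event indicator outside {0, 1}")

    @property
    def genes(self) -> frozenset[int]:
        return frozenset(self.expr.index)

    @property
    def n_samples(self) -> int:
        return self.expr.shape[1]

    def log2p1(self) -> "CohortData":
        """Return a copy with expression transformed to log2(x + 1)."""
        return CohortData(np.log2(self.expr + 1.0), self.time.copy(), self.event.copy())


@dataclass
class CountTable:
    """Per-gene mapped read counts with gene lengths and coding flags."""

    counts: pd.DataFrame          # genes x samples, non-negative integers
    lengths: pd.Series            # base pairs, > 0, indexed by gene
    coding: pd.Series             # bool, indexed by gene

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise DataValidationError("negative read count")
        if not self.lengths.index.equals(self.counts.index):
            raise DataValidationError("lengths index does not match count rows")
        if not self.coding.index.equals(self.counts.index):
            raise DataValidationError("coding index does not match count rows")
        if (self.lengths <= 0).any():
            raise DataValidationError("non-positive gene length")


def fpkm(counts: CountTable) -> pd.DataFrame:
    """FPKM per gene and sample; denominator = total protein-coding reads."""
    totals = counts.counts.loc[counts.coding].sum(axis=0).astype(float)
    zero = totals.index[totals == 0]
    if len(zero):
        raise DegenerateInputError(
            f"sample {zero[0]!r} has zero protein-coding reads"
        )
    return 1e9 * counts.counts.div(totals, axis=1).div(counts.lengths, axis=0)


def fpkm_uq(counts: CountTable) -> pd.DataFrame:
    """FPKM with the per-sample 75th-percentile coding-gene count as denominator.

    The quantile uses linear interpolation between order statistics over
    protein-coding genes only, zeros included.
    """
    coding = counts.counts.loc[counts.coding].astype(float)
    uq = pd.Series(
        np.percentile(coding.values, 75, axis=0), index=coding.columns
    )
    zero = uq.index[uq == 0]
    if len(zero):
        raise DegenerateInputError(
            f"sample {zero[0]!r} has a zero 75th-percentile coding count"
        )
    return 1e9 * counts.counts.div(uq, axis=1).div(counts.lengths, axis=0)


def filter_genes(
    cohort: CohortData, coding: frozenset[int] | set[int], max_missing_frac: float
) -> CohortData:
    """Keep protein-coding genes with an acceptably small missing fraction.

    A gene survives when it is in ``coding`` and its fraction of missing
    samples is strictly below ``max_missing_frac`` (genes with no missing
    values always survive, so a threshold of 0 keeps exactly the complete
    genes). Idempotent.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    frac = cohort.expr.isna().mean(axis=1)
    keep = cohort.expr.index.isin(coding) & ((frac < max_missing_frac) | (frac == 0))
    if not keep.any():
        raise DegenerateInputError("gene filter removed every gene")
    return CohortData(cohort.expr.loc[keep], cohort.time.copy(), cohort.event.copy())


def read_cohort(expr_path: str, clinical_path: str) -> CohortData:
    """Read an expression TSV and a clinical TSV, inner-joined on sample IDs.

    Expression: first column gene ID, header row of sample IDs, NA for
    missing. Clinical: columns ``sample``, ``time``, ``event``. Samples
    absent from either file are dropped (count logged); zero shared
    samples is an error.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    expr.index = expr.index.astype(int)
    if expr.index.duplicated().any():
        dup = expr.index[expr.index.duplicated()][0]
        raise DataValidationError(f"duplicate gene row {dup!r} in {expr_path}")
    clin = pd.read_csv(clinical_path, sep="\t", dtype={"sample": str})
    for col in ("sample", "time", "event"):
        if col not in clin.columns:
            raise DataValidationError(f"clinical table lacks column {col!r}")
    if not clin["event"].isin([0, 1]).all():
        raise DataValidationError("clinical event column outside {0, 1}")
    clin = clin.set_index("sample")
    shared = [s for s in expr.columns if s in clin.index]
    if not shared:
        raise DataValidationError("no shared sample IDs between expression and clinical tables")
    n_dropped = (expr.shape[1] - len(shared)) + (len(clin) - len(shared))
    if n_dropped:
        logger.info("read_cohort: dropped %d sample(s) without a match", n_dropped)
    expr = expr[shared]
    clin = clin.loc[shared]
    return CohortData(
        expr=expr,
        time=clin["time"].astype(float),
        event=clin["event"].astype(int),
    )


def write_cohort(cohort: CohortData, expr_path: str, clinical_path: str) -> None:
    cohort.expr.to_csv(expr_path, sep="\t", index_label="gene")
    clin = pd.DataFrame(
        {"sample": cohort.expr.columns, "time": cohort.time.values, "event": cohort.event.values}
    )
    clin.to_csv(clinical_path, sep="\t", index=False)
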