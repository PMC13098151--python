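"""Within/between-oocyte variance partitioning of half-oocyte proteomes.

For every protein measured in all ``2N`` hemispheres of ``N`` bisected
oocytes, the total sum of squares about the grand mean,

    SS   = sum_{o,h} (x_{o,h} - xbar)^2 ,

is split into a between-oocyte component computed from the per-oocyte
two-half means (each carrying multiplicity 2),

    SSbo = sum_o 2 (xbar_o - xbar)^2 ,

and the within-oocyte remainder

    SSwo = SS - SSbo = sum_o sum_h (x_{o,h} - xbar_o)^2 .

This is the one-way ANOVA decomposition with oocytes as groups and the
two hemispheres as replicates, so ``SSbo, SSwo >= 0`` and the ratio
``SSwo/SS`` lies in [0, 1]: 1 means hemisphere differences dominate,
0 means oocyte-to-oocyte differences dominate.  Proteins whose ratio
exceeds a threshold (0.80 by default, i.e. within-oocyte variation at
least four times the between-oocyte variation) are called regionalized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import CorrelationResult, spearman
from .containers import HalfProteomeMatrix, InvalidInputError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.80

__all__ = [
    "VariancePartition",
    "VariancePartitionResults",
    "VennSummary",
    "filter_complete",
    "partition_variance",
    "implied_fold",
    "compare_sets",
    "compare_ratio_distributions",
]


def filter_complete(matrix: HalfProteomeMatrix) -> HalfProteomeMatrix:
    """Keep only proteins detected in every half; original order preserved.

    Mirrors the completeness filter applied to half-cell LFQ data before
    the sum-of-squares decomposition (missing means not detected, and a
    protein absent from any hemisphere cannot be partitioned).
    """
    complete = matrix.values.notna().all(axis=1)
    kept = matrix.values.index[complete]
    logger.info(
        "completeness filter: %d of %d proteins present in all %d halves",
        len(kept), matrix.n_proteins, len(matrix.half_ids),
    )
    if len(kept) == 0:
        logger.warning("no protein is present in every half")
    return HalfProteomeMatrix(matrix.values.loc[kept], matrix.design, matrix.axis)


class VariancePartition:
    """Per-protein within/between-oocyte sum-of-squares model.

    Parameters
    ----------
    matrix : HalfProteomeMatrix
        Complete matrix (no missing cells; apply :func:`filter_complete`
        first) with at least two oocytes.
    log2 : bool, default False
        Apply a log2 transform to the abundances before partitioning.
        Values must then be strictly positive.
    """

    def __init__(self, matrix: HalfProteomeMatrix, log2: bool = False):
        if matrix.values.isna().any().any():
            raise InvalidInputError(
                "matrix contains missing values; run filter_complete first"
            )
        if matrix.n_oocytes < 2:
            raise InvalidInputError("variance partitioning requires >= 2 oocytes")
        self.matrix = matrix
        self.log2 = log2

    def fit(self) -> "VariancePartitionResults":
        X = self.matrix.values.to_numpy(dtype=float)
        if self.log2:
            if (X <= 0).any():
                raise InvalidInputError("log2 transform requires positive abundances")
            X = np.log2(X)
        oocytes = self.matrix.oocyte_of.to_numpy()
        uniq, inverse = np.unique(oocytes, return_inverse=True)
        n_oo = len(uniq)
        grand = X.mean(axis=1, keepdims=True)
        ss = ((X - grand) ** 2).sum(axis=1)
        # per-oocyte two-half means, each entering SSbo with multiplicity 2
        sums = np.zeros((X.shape[0], n_oo))
        np.add.at(sums.T, inverse, X.T)
        means = sums / 2.0
        ssbo = 2.0 * ((means - grand) ** 2).sum(axis=1)
        sswo = ss - ssbo
        np.clip(sswo, 0.0, None, out=sswo)  # guard tiny negative round-off
        defined = ss > 0
        ratio = np.full(ss.shape, np.nan)
        np.divide(sswo, ss, out=ratio, where=defined)
        n_undef = int((~defined).sum())
        if n_undef:
            logger.warning(
                "%d protein(s) have zero total sum of squares; ratio undefined",
                n_undef,
            )
        table = pd.DataFrame(
            {"SS": ss, "SSbo": ssbo, "SSwo": sswo, "ratio": ratio, "defined": defined},
            index=self.matrix.protein_ids,
        )
        return VariancePartitionResults(table, n_oo, self.matrix.axis, self.log2)


@dataclass
class VariancePartitionResults:
    """Per-protein SS/SSbo/SSwo table with selection helpers."""

    table: pd.DataFrame
    n_oocytes: int
    axis: str
    log2: bool

    @property
    def ratios(self) -> pd.Series:
        return self.table["ratio"]

    def select(
        self, threshold: float = DEFAULT_THRESHOLD, inclusive: bool = True
    ) -> list[str]:
        """Regionalized proteins: ratio >= threshold (or > if not inclusive).

        Sorted by ratio descending, ties broken by protein identifier
        ascending; proteins with undefined ratio are excluded.
        """
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
        tab = self.table[self.table["defined"]]
        mask = tab["ratio"] >= threshold if inclusive else tab["ratio"] > threshold
        hits = tab.loc[mask, "ratio"]
        order = sorted(hits.index, key=lambda p: (-hits[p], str(p)))
        return list(order)

    def summary(self) -> str:
        tab = self.table
        defined = tab[tab["defined"]]
        n_sel = len(self.select())
        lines = [
            "Within/between-oocyte variance partition",
            "=" * 44,
            f"axis:                  {self.axis}",
            f"scale:                 {'log2' if self.log2 else 'as provided'}",
            f"oocytes:               {self.n_oocytes}",
            f"proteins:              {len(tab)}",
            f"ratio defined:         {len(defined)}",
            f"median SSwo/SS:        {defined['ratio'].median():.4f}",
            f"ratio >= {DEFAULT_THRESHOLD:.2f}:          {n_sel}",
            f"implied within/between fold at {DEFAULT_THRESHOLD:.2f}: "
            f"{implied_fold(DEFAULT_THRESHOLD):.1f}",
        ]
        return "\n".join(lines)


def partition_variance(
    matrix: HalfProteomeMatrix, log2: bool = False
) -> VariancePartitionResults:
    """Convenience wrapper: ``VariancePartition(matrix, log2).fit()``."""
    return VariancePartition(matrix, log2=log2).fit()


def implied_fold(threshold: float) -> float:
    """Within/between fold implied by an SSwo/SS threshold.

    ``SSwo/SS = t`` means ``SSwo/SSbo = t/(1-t)``; e.g. a threshold of
    0.80 demands within-oocyte variation four times the between-oocyte
    variation.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(
            f"threshold must lie strictly in (0, 1), got {threshold}"
        )
    return threshold / (1.0 - threshold)


@dataclass(frozen=True)
class VennSummary:
    only_a: int
    only_b: int
    overlap: int

    @property
    def unique_total(self) -> int:
        return self.only_a + self.only_b + self.overlap


def compare_sets(set_a, set_b) -> VennSummary:
    """Two-set Venn summary of regionalized protein lists."""
    a, b = set(set_a), set(set_b)
    inter = a & b
    return VennSummary(len(a - b), len(b - a), len(inter))


def compare_ratio_distributions(
    result_a: VariancePartitionResults, result_b: VariancePartitionResults
) -> CorrelationResult:
    """Spearman correlation of SSwo/SS ratios over shared proteins.

    Compares how two bisection axes rank the same proteins; a weak
    correlation indicates that different protein sets are regionalized
    along the two axes.
    """
    ra = result_a.table.loc[result_a.table["defined"], "ratio"]
    rb = result_b.table.loc[result_b.table["defined"], "ratio"]
    shared = ra.index.intersection(rb.index)
    if len(shared) < 3:
        raise InvalidInputError(
            f"need >= 3 shared proteins with defined ratios, got {len(shared)}"
        )
    return spearman(ra.loc[shared].to_numpy(), rb.loc[shared].to_numpy())
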