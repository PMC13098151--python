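"""Paired twin/cotwin analyses of blastocyst lineage counts and TPM data.

Splitting a 2-cell embryo yields two blastocysts from the sister
blastomeres.  Because neither member of a pair is intrinsically "first",
every paired display and statistic orders the members by a size proxy:
the member with the lower total cell count (or lower *Actb* TPM, which
tracks cell number) is twin 'a', the other is cotwin 'b'.  On top of
that ordering the module provides Spearman correlations of paired
measurements, Wilcoxon signed-rank location tests, and the
delta-vs-delta analysis that asks how large the lineage imbalance is
when the twins have the *same* total cell number.

TPM utilities implement the expression-side conventions: genes are kept
when TPM > 1 in at least three samples and sorted by geometric mean TPM;
incomplete pairs are dropped jointly; absolute twin-cotwin TPM
differences are ranked for export to enrichment tools; and group mean
expression is normalized to a reference group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import CorrelationResult, WilcoxonResult, spearman, wilcoxon_paired
from .containers import LINEAGES, InvalidInputError, TwinPairTable
from .panels import GenePanel

logger = logging.getLogger(__name__)

__all__ = [
    "assign_ab",
    "attach_actb",
    "paired_values",
    "paired_correlation",
    "paired_location_test",
    "delta_analysis",
    "DeltaAnalysisResult",
    "filter_tpm",
    "drop_incomplete_pairs",
    "rank_absolute_differences",
    "normalized_group_means",
    "tpm_pair_correlation",
    "TwinPairModel",
    "PairedImbalanceResults",
]


# ----------------------------------------------------------------------
# a/b ordering
# ----------------------------------------------------------------------

def attach_actb(table: TwinPairTable, gene: str = "Actb") -> TwinPairTable:
    """Copy a gene's TPM row (default *Actb*) into an ``actb_tpm`` column."""
    if table.tpm is None or gene not in table.tpm.index:
        raise InvalidInputError(f"TPM matrix with an {gene!r} row is required")
    data = table.data.copy()
    data["actb_tpm"] = data["sample_id"].map(table.tpm.loc[gene])
    return TwinPairTable(data, table.tpm)


def assign_ab(table: TwinPairTable, key: str = "total_cells") -> TwinPairTable:
    """Order each pair: lower ``key`` value becomes twin 'a'.

    ``key`` is ``"total_cells"`` for count data or ``"actb_tpm"`` for
    transcriptome data.  Ties are broken by sample identifier
    (lexicographic ascending) and logged.  Missing key values raise an
    error naming the pair.
    """
    if key not in table.data.columns:
        raise InvalidInputError(f"key column {key!r} absent from pair table")
    data = table.data.copy()
    roles = pd.Series(index=data.index, dtype=object)
    for pair_id, sub in data.groupby("pair_id", sort=False):
        vals = sub[key]
        if vals.isna().any():
            raise InvalidInputError(
                f"pair {pair_id!r} has a missing {key!r} value"
            )
        if vals.iloc[0] == vals.iloc[1]:
            logger.info(
                "pair %r tied on %s (%s); tie broken by sample_id",
                pair_id, key, vals.iloc[0],
            )
        order = sub.sort_values([key, "sample_id"], kind="mergesort").index
        roles.loc[order[0]] = "a"
        roles.loc[order[1]] = "b"
    data["role"] = roles
    return TwinPairTable(data, table.tpm)


def paired_values(
    table: TwinPairTable, measure: str, group: str | None = None
) -> pd.DataFrame:
    """Wide frame (pair_id x [a, b]) of a measure; incomplete pairs dropped.

    Requires the a/b ordering (``role`` column) from :func:`assign_ab`.
    """
    if "role" not in table.data.columns:
        raise InvalidInputError("run assign_ab before extracting paired values")
    if measure not in table.data.columns:
        raise InvalidInputError(f"measure {measure!r} absent from pair table")
    data = table.data
    if group is not None:
        data = data[data["group"] == group]
    wide = data.pivot(index="pair_id", columns="role", values=measure)
    n_before = len(wide)
    wide = wide.dropna()
    dropped = n_before - len(wide)
    if dropped:
        logger.info("dropped %d pair(s) with missing %s", dropped, measure)
    return wide


def paired_correlation(
    table: TwinPairTable, measure: str, group: str | None = None
) -> CorrelationResult:
    """Spearman correlation of twin-'a' vs cotwin-'b' values across pairs."""
    wide = paired_values(table, measure, group)
    if len(wide) < 3:
        raise InvalidInputError(
            f"need >= 3 complete pairs for {measure!r}, got {len(wide)}"
        )
    return spearman(wide["a"].to_numpy(), wide["b"].to_numpy())


def paired_location_test(
    table: TwinPairTable, measure: str, group: str | None = None
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test of the twin-cotwin differences."""
    wide = paired_values(table, measure, group)
    if len(wide) < 3:
        raise InvalidInputError(
            f"need >= 3 complete pairs for {measure!r}, got {len(wide)}"
        )
    return wilcoxon_paired(wide["a"].to_numpy(), wide["b"].to_numpy())


# ----------------------------------------------------------------------
# delta-vs-delta analysis
# ----------------------------------------------------------------------

@dataclass
class DeltaAnalysisResult:
    """Absolute twin-cotwin differences and their relation to total cells."""

    records: pd.DataFrame
    correlations: dict = field(default_factory=dict)
    restricted_mean: dict = field(default_factory=dict)
    restricted_range: dict = field(default_factory=dict)
    n_restricted: int = 0
    window: int = 0

    def summary(self) -> str:
        lines = ["Twin-cotwin delta analysis", "=" * 36,
                 f"pairs: {len(self.records)}",
                 f"pairs with |delta total| <= {self.window}: {self.n_restricted}"]
        for lin in LINEAGES:
            corr = self.correlations[lin]
            mean = self.restricted_mean[lin]
            mean_s = "undefined" if mean is None else f"{mean:.2f}"
            lines.append(
                f"{lin:<22} rho(d_lineage, d_total) = {corr.rho:+.3f} "
                f"(p = {corr.pvalue:.4f}); mean delta at matched totals = {mean_s}"
            )
        return "\n".join(lines)


def delta_analysis(
    table: TwinPairTable, group: str | None = None, window: int = 0
) -> DeltaAnalysisResult:
    """Per-pair |delta| records, their Spearman link to |delta total|, and
    the mean lineage imbalance among pairs with equal totals.

    ``window`` widens "equal totals" to ``|delta total| <= window``
    (default 0, i.e. exactly equal).  When no pair qualifies the
    restricted mean is reported as ``None`` (undefined).
    """
    data = table.data
    if group is not None:
        data = data[data["group"] == group]
    needed = ("total_cells",) + LINEAGES
    if data[list(needed)].isna().any().any():
        raise InvalidInputError("delta analysis requires complete counts")
    rows = []
    for pair_id, sub in data.groupby("pair_id", sort=False):
        rec = {"pair_id": pair_id,
               "delta_total": abs(sub["total_cells"].iloc[0]
                                  - sub["total_cells"].iloc[1])}
        for lin in LINEAGES:
            rec[f"delta_{lin}"] = abs(sub[lin].iloc[0] - sub[lin].iloc[1])
        rows.append(rec)
    records = pd.DataFrame(rows)
    at_zero = records[records["delta_total"] <= window]
    result = DeltaAnalysisResult(records=records, n_restricted=len(at_zero),
                                 window=window)
    for lin in LINEAGES:
        col = f"delta_{lin}"
        result.correlations[lin] = spearman(
            records[col].to_numpy(), records["delta_total"].to_numpy()
        )
        if len(at_zero):
            result.restricted_mean[lin] = float(at_zero[col].mean())
            result.restricted_range[lin] = (float(at_zero[col].min()),
                                            float(at_zero[col].max()))
        else:
            result.restricted_mean[lin] = None
            result.restricted_range[lin] = None
    return result


# ----------------------------------------------------------------------
# TPM utilities
# ----------------------------------------------------------------------

def filter_tpm(
    tpm: pd.DataFrame, min_tpm: float = 1.0, min_samples: int = 3
) -> pd.DataFrame:
    """Keep genes with TPM strictly above ``min_tpm`` in >= ``min_samples``
    samples, then sort by geometric mean TPM descending.

    For a retained gene that still has zeros the geometric mean is taken
    over its positive values only (logged); ties in the geometric mean
    are broken by gene symbol.
    """
    if (tpm.fillna(0) < 0).any().any():
        raise InvalidInputError("TPM values must be non-negative")
    keep = (tpm > min_tpm).sum(axis=1) >= min_samples
    out = tpm.loc[keep]
    logger.info("TPM filter: %d of %d genes retained (>%g in >= %d samples)",
                keep.sum(), len(tpm), min_tpm, min_samples)
    with np.errstate(divide="ignore"):
        logs = np.log(out.to_numpy(dtype=float))
    masked = np.ma.masked_invalid(logs)
    gmean = pd.Series(np.exp(masked.mean(axis=1)).filled(0.0), index=out.index)
    n_zero = int((out <= 0).any(axis=1).sum())
    if n_zero:
        logger.info(
            "%d retained gene(s) contain zeros; geometric mean over "
            "positive values only", n_zero,
        )
    order = sorted(out.index, key=lambda g: (-gmean[g], str(g)))
    return out.loc[order]


def drop_incomplete_pairs(table: TwinPairTable, failed_samples=()) -> TwinPairTable:
    """Remove both members of any pair with a failed member.

    ``failed_samples`` lists samples excluded upstream (QC, mapping
    rate); a sample missing from the attached TPM matrix also counts as
    failed when a TPM matrix is present.
    """
    failed = set(failed_samples)
    if table.tpm is not None:
        failed |= set(table.data["sample_id"]) - set(table.tpm.columns)
    bad_pairs = sorted(
        table.data.loc[table.data["sample_id"].isin(failed), "pair_id"].unique()
    )
    if bad_pairs:
        logger.info("dropping incomplete pairs: %s", bad_pairs)
    data = table.data[~table.data["pair_id"].isin(bad_pairs)].reset_index(drop=True)
    return table.with_data(data)


def rank_absolute_differences(
    table: TwinPairTable, genes=None, group: str | None = None
) -> pd.Series:
    """Genes ranked by mean |TPM_a - TPM_b| descending (ties by symbol).

    This is the unsupervised ranking exported to GO-enrichment tools; it
    only requires the pairing, not the a/b ordering (|a-b| is symmetric).
    """
    if table.tpm is None:
        raise InvalidInputError("pair table has no TPM matrix")
    data = table.data
    if group is not None:
        data = data[data["group"] == group]
    tpm = table.tpm if genes is None else table.tpm.loc[list(genes)]
    diffs = []
    for pair_id, sub in data.groupby("pair_id", sort=False):
        ids = sub["sample_id"].tolist()
        if not all(s in tpm.columns for s in ids):
            continue
        diffs.append((tpm[ids[0]] - tpm[ids[1]]).abs())
    if not diffs:
        raise InvalidInputError("no complete pair with TPM data")
    mean_diff = pd.concat(diffs, axis=1).mean(axis=1)
    order = sorted(mean_diff.index, key=lambda g: (-mean_diff[g], str(g)))
    return mean_diff.loc[order].rename("mean_abs_tpm_diff")


def normalized_group_means(
    tpm: pd.DataFrame,
    sample_groups,
    panel: GenePanel,
    reference_group: str,
) -> pd.DataFrame:
    """Per-gene mean TPM by group, expressed relative to a reference group.

    The reference group's ratio is 1 by construction; a ratio of 0.5
    means the group's mean expression is half the reference's.
    """
    groups = pd.Series(sample_groups)
    groups = groups[groups.index.intersection(tpm.columns)]
    if reference_group not in set(groups):
        raise InvalidInputError(
            f"reference group {reference_group!r} has no samples"
        )
    present = [g for g in panel if g in tpm.index]
    absent = sorted(set(panel.genes) - set(present))
    if absent:
        logger.info("panel %r: %d gene(s) absent from TPM matrix: %s",
                    panel.name, len(absent), absent)
    if not present:
        raise InvalidInputError(f"no gene of panel {panel.name!r} in TPM matrix")
    sub = tpm.loc[present]
    means = sub.T.groupby(groups).mean().T  # genes x groups
    ref = means[reference_group]
    if (ref == 0).any():
        zero = ref.index[ref == 0].tolist()
        raise InvalidInputError(
            f"reference group mean is zero for genes {zero}"
        )
    return means.div(ref, axis=0)


def tpm_pair_correlation(
    table: TwinPairTable,
    genes=None,
    group: str | None = None,
    log2: bool = True,
    pseudocount: float = 1.0,
) -> CorrelationResult:
    """Spearman correlation of twin-'a' vs cotwin-'b' TPM, pooled over
    genes and pairs (the scatter-plot statistic for a gene family).

    Values are log2(TPM + pseudocount) by default, matching how wide
    dynamic-range expression data are displayed.
    """
    if table.tpm is None:
        raise InvalidInputError("pair table has no TPM matrix")
    if "role" not in table.data.columns:
        raise InvalidInputError("run assign_ab before correlating TPM values")
    data = table.data
    if group is not None:
        data = data[data["group"] == group]
    tpm = table.tpm if genes is None else table.tpm.loc[
        [g for g in genes if g in table.tpm.index]
    ]
    xs, ys = [], []
    for pair_id, sub in data.groupby("pair_id", sort=False):
        sub = sub.set_index("role")
        sa, sb = sub.loc["a", "sample_id"], sub.loc["b", "sample_id"]
        if sa not in tpm.columns or sb not in tpm.columns:
            continue
        xs.append(tpm[sa].to_numpy(dtype=float))
        ys.append(tpm[sb].to_numpy(dtype=float))
    if not xs:
        raise InvalidInputError("no complete pair with TPM data")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if log2:
        x = np.log2(x + pseudocount)
        y = np.log2(y + pseudocount)
    return spearman(x, y)


# ----------------------------------------------------------------------
# model-style front end
# ----------------------------------------------------------------------

@dataclass
class PairedImbalanceResults:
    """Correlation + location test + delta analysis for one measure."""

    measure: str
    group: str | None
    n_pairs: int
    correlation: CorrelationResult
    location: WilcoxonResult
    deltas: DeltaAnalysisResult | None

    def summary(self) -> str:
        lines = [
            f"Paired twin-cotwin analysis: {self.measure}"
            + (f" [{self.group}]" if self.group else ""),
            "=" * 44,
            f"complete pairs:        {self.n_pairs}",
            f"Spearman rho (a vs b): {self.correlation.rho:+.4f} "
            f"(p = {self.correlation.pvalue:.4f})",
            f"Wilcoxon signed-rank:  W = {self.location.statistic:.1f}, "
            f"p = {self.location.pvalue:.4f} "
            f"({self.location.n_zero} zero difference(s) dropped)",
        ]
        if self.deltas is not None:
            mean = self.deltas.restricted_mean.get(self.measure)
            if mean is not None:
                lines.append(
                    f"mean |delta {self.measure}| at matched totals: {mean:.2f} "
                    f"(n = {self.deltas.n_restricted})"
                )
        return "\n".join(lines)


class TwinPairModel:
    """Statsmodels-style front end for the paired twin analyses.

    Construction assigns the a/b ordering by ``key``; :meth:`fit` runs
    the Spearman correlation and the Wilcoxon location test for one
    measure (plus the delta analysis for lineage counts).
    """

    def __init__(self, table: TwinPairTable, key: str = "total_cells"):
        self.table = assign_ab(table, key=key)
        self.key = key

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, tpm: pd.DataFrame | None = None,
                       key: str = "total_cells") -> "TwinPairModel":
        return cls(TwinPairTable(data, tpm), key=key)

    def fit(self, measure: str = "epiblast",
            group: str | None = None) -> PairedImbalanceResults:
        corr = paired_correlation(self.table, measure, group)
        loc = paired_location_test(self.table, measure, group)
        deltas = None
        if measure in LINEAGES:
            deltas = delta_analysis(self.table, group=group)
        return PairedImbalanceResults(
            measure=measure, group=group, n_pairs=corr.n,
            correlation=corr, location=loc, deltas=deltas,
        )
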