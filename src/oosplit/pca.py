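"""PCA of a selected-protein submatrix and hemisphere-class resolution.

The question answered here is whether hemisphere classes (A vs V, or L
vs R) are *resolved* in a principal-component projection of the halves:
"resolved" is operationalized as perfect linear separability of the two
classes on PC1, on PC2, or in the PC1-PC2 plane, with the mean
silhouette width reported as a graded separation score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .containers import HalfProteomeMatrix, InvalidInputError
from .varpart import VariancePartitionResults

logger = logging.getLogger(__name__)

#: threshold grid used by :func:`threshold_scan` (ascending)
DEFAULT_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))

__all__ = [
    "project",
    "assess_resolution",
    "threshold_scan",
    "PcaResolutionReport",
    "ThresholdScanResult",
]


def project(
    matrix: HalfProteomeMatrix,
    proteins=None,
    standardize: bool = True,
    n_components: int = 2,
    log2: bool = False,
) -> pd.DataFrame:
    """Principal-component scores of the halves on a protein subset.

    Proteins are centred and (by default) scaled to unit variance across
    halves before the decomposition; zero-variance proteins are dropped
    with a warning.  Returns a halves x [PC1, PC2, ...] frame.
    """
    sub = matrix if proteins is None else matrix.subset(proteins)
    if sub.values.isna().any().any():
        raise InvalidInputError("PCA requires complete values; filter first")
    if len(sub.half_ids) < 3:
        raise InvalidInputError("PCA requires at least 3 halves")
    X = sub.values.to_numpy(dtype=float).T  # halves x proteins
    if log2:
        if (X <= 0).any():
            raise InvalidInputError("log2 transform requires positive abundances")
        X = np.log2(X)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        dropped = sub.protein_ids[~keep].tolist()
        logger.warning("dropping %d zero-variance protein(s): %s",
                       len(dropped), dropped[:5])
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise InvalidInputError("no protein with non-zero variance")
    X = X - X.mean(axis=0)
    if standardize:
        X = X / sd
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=sub.half_ids, columns=cols)


def _linearly_separable(X: np.ndarray, y: np.ndarray) -> bool:
    """Exact linear-separability test via an LP feasibility problem.

    Feasible iff there exist w, b with ``y_i (w . x_i + b) >= 1`` for all
    halves (y in {-1, +1}).
    """
    n, d = X.shape
    A = -y[:, None] * np.hstack([X, np.ones((n, 1))])
    res = linprog(
        c=np.zeros(d + 1),
        A_ub=A,
        b_ub=-np.ones(n),
        bounds=[(None, None)] * (d + 1),
        method="highs",
    )
    return bool(res.success)


@dataclass
class PcaResolutionReport:
    """Outcome of the hemisphere-resolution assessment."""

    separable: bool
    separation_score: float
    best_axis: str | None
    n_proteins: int | None
    scores: pd.DataFrame = field(repr=False)
    labels: pd.Series = field(repr=False)

    def summary(self) -> str:
        lines = [
            "PCA hemisphere resolution",
            "=" * 32,
            f"proteins used:     {self.n_proteins}",
            f"halves:            {len(self.scores)}",
            f"classes:           {sorted(self.labels.unique())}",
            f"resolved:          {self.separable}",
            f"resolving axis:    {self.best_axis}",
            f"mean silhouette:   {self.separation_score:.4f}",
        ]
        return "\n".join(lines)


def assess_resolution(
    scores: pd.DataFrame, labels, n_proteins: int | None = None
) -> PcaResolutionReport:
    """Decide whether two hemisphere classes separate in the PC projection.

    ``separable`` is true iff PC1 alone, PC2 alone, or the PC1-PC2 plane
    admits a linear boundary misclassifying no half.  The separation
    score is the mean silhouette width on the PC1-PC2 plane (Euclidean).
    """
    labels = pd.Series(labels, index=scores.index) if not isinstance(
        labels, pd.Series
    ) else labels.loc[scores.index]
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise InvalidInputError(f"exactly 2 label classes required, got {classes}")
    counts = labels.value_counts()
    if (counts < 2).any():
        raise InvalidInputError(
            f"each class needs >= 2 halves, got {counts.to_dict()}"
        )
    y = np.where(labels.to_numpy() == classes[0], -1.0, 1.0)
    axes = [c for c in ("PC1", "PC2") if c in scores.columns]
    best_axis = None
    for ax in axes:
        x = scores[ax].to_numpy()
        lo, hi = x[y < 0], x[y > 0]
        if lo.max() < hi.min() or hi.max() < lo.min():
            best_axis = ax
            break
    if best_axis is None and len(axes) == 2:
        if _linearly_separable(scores[axes].to_numpy(), y):
            best_axis = "PC1-PC2"
    plane = scores[axes].to_numpy()
    score = float(silhouette_score(plane, labels.to_numpy(), metric="euclidean"))
    return PcaResolutionReport(
        separable=best_axis is not None,
        separation_score=score,
        best_axis=best_axis,
        n_proteins=n_proteins,
        scores=scores,
        labels=labels,
    )


@dataclass
class ThresholdScanResult:
    """Per-threshold resolution report from :func:`threshold_scan`."""

    best_threshold: float | None
    report: pd.DataFrame  # threshold, n_selected, separable, silhouette

    def summary(self) -> str:
        out = ["Threshold scan (SSwo/SS selection vs PCA resolution)",
               "=" * 52,
               self.report.to_string(index=False),
               f"lowest resolving threshold: {self.best_threshold}"]
        return "\n".join(out)


def threshold_scan(
    result: VariancePartitionResults,
    matrix: HalfProteomeMatrix,
    grid=DEFAULT_GRID,
    standardize: bool = True,
    log2: bool = False,
) -> ThresholdScanResult:
    """Scan selection thresholds for the smallest one that still resolves.

    Thresholds are evaluated from the most stringent down; empty
    selections (or selections too small for a PCA) are marked
    unresolvable and the scan continues.  Hemisphere labels come from
    the matrix design.
    """
    grid = sorted(float(g) for g in grid)
    if any(not 0.0 < g < 1.0 for g in grid):
        raise ValueError("grid thresholds must lie strictly in (0, 1)")
    labels = matrix.hemisphere_of
    rows = []
    best = None
    for thr in reversed(grid):
        selected = result.select(thr)
        row = {"threshold": thr, "n_selected": len(selected),
               "separable": False, "silhouette": np.nan}
        if selected:
            try:
                scores = project(matrix, selected, standardize=standardize,
                                 log2=log2)
                rep = assess_resolution(scores, labels)
                rep.n_proteins = len(selected)
                row["separable"] = rep.separable
                row["silhouette"] = rep.separation_score
            except InvalidInputError as exc:
                logger.info("threshold %.2f unresolvable: %s", thr, exc)
        rows.append(row)
        if row["separable"]:
            best = thr  # keep descending: lowest resolving wins
    report = pd.DataFrame(rows).sort_values("threshold").reset_index(drop=True)
    return ThresholdScanResult(best, report)
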