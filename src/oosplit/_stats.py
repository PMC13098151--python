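"""Non-parametric paired statistics shared by the twin and proteome analyses.

Spearman's rho uses an exact permutation null for n <= 9 and the usual
t approximation above; the Wilcoxon signed-rank test uses the exact null
for n <= 25 and the normal approximation with continuity correction
above.  Zero differences are dropped before the signed-rank test and
their count is reported.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

SPEARMAN_EXACT_MAX_N = 9
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    pvalue: float
    n: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    pvalue: float
    n_used: int
    n_zero: int


def _rank(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    For n <= 9 the p-value is exact, obtained by enumerating all n!
    permutations of one margin (ties handled through average ranks);
    otherwise the t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    rx = _rank(x)
    ry = _rank(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    if denom == 0:
        return CorrelationResult(np.nan, np.nan, n)
    rho = float((rx_c * ry_c).sum() / denom)
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        ry_perm = ry_c[perms]  # (n!, n)
        rhos = ry_perm @ rx_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(rho, p, n)


def wilcoxon_paired(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (their count is reported); if every
    difference is zero the test is degenerate and ``p = 1`` is returned
    with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be one-dimensional and equally long")
    d = b - a
    n_zero = int(np.sum(d == 0))
    d = d[d != 0]
    n = d.size
    if n == 0:
        logger.warning("all paired differences are zero; signed-rank p set to 1")
        return WilcoxonResult(0.0, 1.0, 0, n_zero)
    method = "exact" if n <= WILCOXON_EXACT_MAX_N else "approx"
    kwargs = {} if method == "exact" else {"correction": True}
    try:
        res = stats.wilcoxon(d, alternative="two-sided", method=method, **kwargs)
    except (ValueError, NotImplementedError):
        # exact null unavailable (e.g. tied ranks on some scipy versions)
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n, n_zero)
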