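"""Bisection-accuracy volumetrics and first-cleavage angle analysis.

Each post-bisection half is treated as a sphere measured by its own
circumference: ``c = 2*pi*r`` gives the radius and ``V = 4/3*pi*r^3``
the volume, so ``V = c^3 / (6*pi^2)``.  The accuracy of a bisection is
summarized by the larger/smaller volume ratio (1 for a perfect split)
and the equivalent percent difference.

Cleavage angles are measured between the animal-vegetal (A-V) axis and
the first cleavage axis, folded into [0, 90] degrees (an axis has no
direction).  The "perpendicular band" is 60-90 degrees inclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import InvalidInputError

#: angle band (degrees, inclusive) counted as perpendicular cleavage
PERPENDICULAR_BAND = (60.0, 90.0)

__all__ = [
    "BisectionGeometry",
    "volume_from_circumference",
    "hemisphere_ratio",
    "fold_angle",
    "perpendicular_fraction",
    "angle_histogram",
    "bisection_summary",
]


def volume_from_circumference(c: float) -> float:
    """Sphere volume (um^3) from a circumference (um): ``V = c^3/(6*pi^2)``."""
    if not c > 0:
        raise InvalidInputError(f"circumference must be positive, got {c}")
    return float(c) ** 3 / (6.0 * math.pi**2)


@dataclass(frozen=True)
class BisectionGeometry:
    """Volumetric record for one pair of sister hemispheres."""

    circumference_1: float
    circumference_2: float
    radius_1: float
    radius_2: float
    volume_1: float
    volume_2: float
    ratio: float
    percent_diff: float


def hemisphere_ratio(c1: float, c2: float) -> BisectionGeometry:
    """Full volumetric record from two hemisphere circumferences (um).

    ``ratio`` is larger/smaller volume (>= 1, symmetric in its
    arguments, and equal to ``(max(c)/min(c))**3``); ``percent_diff`` is
    ``(ratio - 1) * 100``.
    """
    v1 = volume_from_circumference(c1)
    v2 = volume_from_circumference(c2)
    ratio = max(v1, v2) / min(v1, v2)
    return BisectionGeometry(
        circumference_1=float(c1),
        circumference_2=float(c2),
        radius_1=float(c1) / (2.0 * math.pi),
        radius_2=float(c2) / (2.0 * math.pi),
        volume_1=v1,
        volume_2=v2,
        ratio=ratio,
        percent_diff=(ratio - 1.0) * 100.0,
    )


def bisection_summary(pairs: pd.DataFrame) -> dict:
    """Mean/SD of the volume ratio over a (c1_um, c2_um) pair table."""
    records = [hemisphere_ratio(r.c1_um, r.c2_um) for r in pairs.itertuples()]
    ratios = np.array([r.ratio for r in records])
    return {
        "n_pairs": len(ratios),
        "mean_ratio": float(ratios.mean()),
        "sd_ratio": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        "mean_percent_diff": float((ratios - 1.0).mean() * 100.0),
        "sd_percent_diff": (
            float((ratios - 1.0).std(ddof=1) * 100.0) if len(ratios) > 1 else 0.0
        ),
    }


def fold_angle(raw_angle: float) -> float:
    """Fold any finite angle (degrees) into [0, 90].

    Reduce modulo 180 (an axis repeats every half-turn), then map
    angles above 90 to their supplement.  Idempotent on [0, 90].
    """
    a = np.asarray(raw_angle, dtype=float)
    if not np.isfinite(a).all():
        raise InvalidInputError("angle must be finite")
    a = np.mod(a, 180.0)
    a = np.where(a > 90.0, 180.0 - a, a)
    return float(a) if a.ndim == 0 else a


def perpendicular_fraction(
    records: pd.DataFrame,
    band: tuple[float, float] = PERPENDICULAR_BAND,
    pool: tuple[str, ...] | None = None,
) -> dict[str, float]:
    """Per-ICSI-site fraction of cleavage angles inside the band.

    ``records`` needs columns ``icsi_site`` and ``angle_deg`` (already
    folded); band endpoints are inclusive.  ``pool`` optionally adds a
    pooled entry (e.g. ``("ipsilateral", "contralateral")`` for the two
    polar injection sites) keyed by the joined names.
    """
    lo, hi = band
    if not 0.0 <= lo < hi <= 90.0:
        raise InvalidInputError(f"band must satisfy 0 <= lo < hi <= 90, got {band}")
    angles = records["angle_deg"].astype(float)
    if (angles < 0).any() or (angles > 90).any():
        raise InvalidInputError("angles must be folded into [0, 90] first")
    inside = (angles >= lo) & (angles <= hi)
    out: dict[str, float] = {}
    for site, sub in records.groupby("icsi_site"):
        out[str(site)] = float(inside.loc[sub.index].mean())
    if pool:
        mask = records["icsi_site"].isin(pool)
        if not mask.any():
            raise InvalidInputError(f"no record in pooled groups {pool}")
        out["+".join(pool)] = float(inside.loc[mask].mean())
    return out


def angle_histogram(
    records: pd.DataFrame, bin_width: float = 10.0
) -> pd.DataFrame:
    """Decade-bin angle counts per ICSI site (last bin closed at 90)."""
    edges = np.arange(0.0, 90.0 + bin_width, bin_width)
    rows = {}
    for site, sub in records.groupby("icsi_site"):
        counts, _ = np.histogram(sub["angle_deg"], bins=edges)
        rows[str(site)] = counts
    labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 2)]
    labels.append(f"[{edges[-2]:g},{edges[-1]:g}]")
    return pd.DataFrame(rows, index=labels)
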