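"""Synthetic data with the statistical structure the analyses assume.

Three generators emulate the three experimental readouts:

* :func:`generate_half_proteomes` - LFQ-like abundances for the two
  hemispheres of ``N`` bisected oocytes.  Log2 abundances are the sum of
  a per-protein baseline, a per-protein-per-oocyte biological offset, a
  per-half residual noise term, a hemisphere effect carried consistently
  by a small regionalized subset, and a per-oocyte volume-split factor
  that scales all abundances of a half jointly (the bisection error).
  Values are returned on the linear intensity scale; detection dropout
  is completely at random.
* :func:`generate_twin_pairs` - twin blastocyst pairs with ~50 total
  cells each, an epiblast of ~5 cells whose twin-cotwin difference has a
  configurable group-dependent magnitude *independent of* the total-cell
  difference, balanced primitive endoderm, trophectoderm absorbing the
  remainder, ES-colony counts, and a gene x sample TPM matrix in which
  *Actb* scales with total cell number while other transcripts do not
  track the lineage counts.
* :func:`generate_angles` / :func:`generate_circumference_pairs` - first
  cleavage angles biased into the perpendicular 60-90 degree band for
  polar (ipsilateral/contralateral) injections, and hemisphere
  circumference pairs whose volume split reproduces a ~8% mean
  larger/smaller excess.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    EQUATORIAL,
    HEMISPHERES,
    MERIDIONAL,
    HalfProteomeMatrix,
    TwinPairTable,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "ProteomeSimConfig",
    "TwinSimConfig",
    "AngleSimConfig",
    "GeometrySimConfig",
    "generate_half_proteomes",
    "generate_twin_pairs",
    "generate_angles",
    "generate_circumference_pairs",
]


class ConfigError(ValueError):
    """Raised for an invalid simulation-configuration field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


def _require(cond: bool, fieldname: str, message: str) -> None:
    if not cond:
        raise ConfigError(fieldname, message)


# ----------------------------------------------------------------------
# half-oocyte proteomes
# ----------------------------------------------------------------------

@dataclass
class ProteomeSimConfig:
    """Generative settings for half-oocyte LFQ matrices.

    Defaults mirror the scale of the real experiment: 6 oocytes per
    bisection axis, ~1400 proteins detected in every hemisphere, ~5% of
    them regionalized, and a volume split whose larger/smaller ratio
    averages ~1.08.
    """

    n_oocytes: int = 6
    n_proteins: int = 1400
    frac_regionalized: float = 0.05
    mean_log_abundance: float = 20.0   # log2 LFQ intensity
    sigma_protein: float = 2.5         # SD of per-protein baseline (log2)
    sigma_between: float = 0.3         # SD of per-oocyte offset (log2)
    sigma_noise: float = 0.1           # SD of per-half residual (log2)
    hemisphere_effect: float = 1.5     # log2 offset on one hemisphere
    bisection_cv: float = 0.093        # CV of the half/half volume split
    missing_rate: float = 0.05
    axis: str = EQUATORIAL
    seed: int = 0

    def __post_init__(self):
        _require(self.n_oocytes >= 2, "n_oocytes", "must be >= 2")
        _require(self.n_proteins >= 1, "n_proteins", "must be >= 1")
        _require(0.0 <= self.frac_regionalized <= 1.0,
                 "frac_regionalized", "must lie in [0, 1]")
        for name in ("sigma_protein", "sigma_between", "sigma_noise",
                     "bisection_cv"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(0.0 <= self.missing_rate < 1.0,
                 "missing_rate", "must lie in [0, 1)")
        _require(self.axis in (EQUATORIAL, MERIDIONAL),
                 "axis", f"must be one of {(EQUATORIAL, MERIDIONAL)}")


def generate_half_proteomes(
    config: ProteomeSimConfig,
) -> tuple[HalfProteomeMatrix, set[str]]:
    """Simulate a half-oocyte proteome matrix; returns (matrix, truth set).

    Exactly ``round(frac_regionalized * n_proteins)`` proteins carry the
    hemisphere effect.  For an equatorial axis the effect sits on the
    animal (A) hemisphere of every oocyte; for a meridional axis the
    enriched side is drawn per oocyte, reflecting that the L/R labelling
    is arbitrary with respect to any real intracellular gradient, so the
    effect inflates within-oocyte variance without aligning with the
    labels.
    """
    rng = np.random.default_rng(config.seed)
    P, N = config.n_proteins, config.n_oocytes
    hems = HEMISPHERES[config.axis]
    protein_ids = pd.Index([f"P{i + 1:04d}" for i in range(P)], name="protein_id")
    half_ids = [f"oo{o + 1}_{h}" for o in range(N) for h in hems]
    design = pd.DataFrame(
        {
            "oocyte": [f"oo{o + 1}" for o in range(N) for _ in hems],
            "hemisphere": [h for _ in range(N) for h in hems],
        },
        index=pd.Index(half_ids, name="half_id"),
    )

    n_truth = round(config.frac_regionalized * P)
    truth_idx = rng.choice(P, size=n_truth, replace=False)
    truth = {protein_ids[i] for i in truth_idx}

    baseline = config.mean_log_abundance + rng.normal(0, config.sigma_protein, P)
    oocyte_offset = rng.normal(0, config.sigma_between, (P, N))
    noise = rng.normal(0, config.sigma_noise, (P, 2 * N))

    log2 = baseline[:, None] + np.repeat(oocyte_offset, 2, axis=1) + noise

    # hemisphere effect: +effect on the enriched side of truth proteins
    if n_truth and config.hemisphere_effect:
        if config.axis == EQUATORIAL:
            enriched = np.zeros(N, dtype=int)        # always the A half
        else:
            enriched = rng.integers(0, 2, N)         # arbitrary side per oocyte
        cols = 2 * np.arange(N) + enriched
        eff = np.zeros((P, 2 * N))
        eff[np.ix_(truth_idx, cols)] = config.hemisphere_effect
        log2 = log2 + eff

    # volume split: one multiplicative factor per half, shared by all
    # proteins of that half; ln-scale half-difference g gives halves
    # e^{+g/2} and e^{-g/2}, so larger/smaller volume ratio = e^{|g|}
    if config.bisection_cv:
        g = rng.normal(0, config.bisection_cv, N)
        per_half = np.repeat(g / 2.0, 2)
        per_half[1::2] *= -1.0
        log2 = log2 + per_half[None, :] / math.log(2.0)

    values = np.power(2.0, log2)
    if config.missing_rate:
        mask = rng.random((P, 2 * N)) < config.missing_rate
        values = np.where(mask, np.nan, values)
    matrix = HalfProteomeMatrix(
        pd.DataFrame(values, index=protein_ids, columns=design.index),
        design,
        config.axis,
    )
    return matrix, truth


# ----------------------------------------------------------------------
# twin blastocyst pairs
# ----------------------------------------------------------------------

@dataclass
class TwinSimConfig:
    """Generative settings for twin blastocyst pair tables.

    ``imbalance_by_group`` is the expected |twin - cotwin| epiblast
    difference at matched total cell numbers; the epiblast difference is
    drawn independently of the total-cell difference.  Defaults follow
    the observed scale: twins of ~50 total cells, epiblasts of ~5 cells,
    and a 2-3 cell epiblast imbalance that is largest for equatorial
    injection.
    """

    n_pairs_per_group: int = 20
    groups: tuple[str, ...] = ("ipsilateral", "equatorial", "contralateral")
    mean_total: float = 50.0
    total_sd: float = 5.0              # SD of the pair-level mean total
    within_pair_total_sd: float = 3.0  # SD of the twin-cotwin total difference
    mean_epi: float = 5.0
    epi_sd: float = 1.0
    mean_pe: float = 8.0
    pe_sd: float = 0.8
    imbalance_by_group: dict = field(
        default_factory=lambda: {
            "ipsilateral": 2.0, "equatorial": 2.5, "contralateral": 2.0,
        }
    )
    actb_per_cell: float = 100.0       # TPM units per cell
    actb_noise_cv: float = 0.05
    es_efficiency: float = 0.7         # P(epiblast cell -> ES colony)
    n_filler_genes: int = 200
    tpm_noise_sd: float = 0.25         # log2 SD of per-sample TPM noise
    seed: int = 0

    def __post_init__(self):
        _require(self.n_pairs_per_group >= 1, "n_pairs_per_group", "must be >= 1")
        _require(len(self.groups) >= 1, "groups", "must be non-empty")
        _require(self.mean_epi + self.mean_pe <= self.mean_total,
                 "mean_epi", "mean_epi + mean_pe must not exceed mean_total")
        missing = set(self.groups) - set(self.imbalance_by_group)
        _require(not missing, "imbalance_by_group",
                 f"missing groups {sorted(missing)}")
        _require(all(v >= 0 for v in self.imbalance_by_group.values()),
                 "imbalance_by_group", "magnitudes must be >= 0")
        for name in ("total_sd", "within_pair_total_sd", "epi_sd", "pe_sd",
                     "actb_per_cell", "actb_noise_cv", "tpm_noise_sd"):
            _require(getattr(self, name) >= 0, name, "must be >= 0")
        _require(0.0 <= self.es_efficiency <= 1.0,
                 "es_efficiency", "must lie in [0, 1]")
        _require(self.n_filler_genes >= 0, "n_filler_genes", "must be >= 0")


def _clamp_count(x: float, what: str) -> int:
    v = int(round(x))
    if v < 0:
        logger.warning("negative %s after noise clamped to 0", what)
        v = 0
    return v


def generate_twin_pairs(config: TwinSimConfig) -> TwinPairTable:
    """Simulate a twin-pair table (counts, ES colonies, Actb, TPM matrix).

    The half-normal draw for the epiblast difference has expectation
    equal to ``imbalance_by_group[group]`` before rounding to whole
    cells; its sign, and which member receives the larger total, are
    independent coin flips, so the a/b ordering is decided only by the
    realized counts.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in config.groups:
        imb = config.imbalance_by_group[group]
        for p in range(config.n_pairs_per_group):
            pair_id = f"{group}_p{p + 1:02d}"
            total_mid = rng.normal(config.mean_total, config.total_sd)
            d_tot = rng.normal(0, config.within_pair_total_sd)
            epi_mid = rng.normal(config.mean_epi, config.epi_sd)
            # half-normal with mean `imb`, random sign
            d_epi = abs(rng.normal(0, imb * math.sqrt(math.pi / 2.0)))
            d_epi *= rng.choice([-1.0, 1.0])
            pe_mid = rng.normal(config.mean_pe, config.pe_sd)
            for m, sign in (("1", +0.5), ("2", -0.5)):
                total = _clamp_count(total_mid + sign * d_tot, "total_cells")
                epi = _clamp_count(epi_mid + sign * d_epi, "epiblast")
                pe = _clamp_count(pe_mid + rng.normal(0, config.pe_sd / 2.0),
                                  "primitive_endoderm")
                epi = min(epi, total)
                pe = min(pe, total - epi)
                te = total - epi - pe
                es = int(rng.binomial(epi, config.es_efficiency))
                actb = config.actb_per_cell * total * (
                    1.0 + rng.normal(0, config.actb_noise_cv)
                )
                rows.append(
                    {
                        "pair_id": pair_id,
                        "sample_id": f"{pair_id}_{m}",
                        "group": group,
                        "total_cells": total,
                        "epiblast": epi,
                        "primitive_endoderm": pe,
                        "trophectoderm": te,
                        "es_colonies": es,
                        "actb_tpm": max(actb, 0.0),
                    }
                )
    data = pd.DataFrame(rows)
    tpm = _simulate_tpm(data, config, rng)
    return TwinPairTable(data, tpm)


def _simulate_tpm(data: pd.DataFrame, config: TwinSimConfig,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Gene x sample TPM matrix: *Actb* tracks total cells, the rest are
    per-gene lognormal levels with sample noise (no count coupling)."""
    from .panels import all_panels

    genes: list[str] = []
    for panel in all_panels().values():
        genes.extend(g for g in panel if g not in genes)
    genes.extend(f"G{i + 1:04d}" for i in range(config.n_filler_genes))
    base = np.power(2.0, rng.normal(5.0, 2.0, len(genes)))  # ~1-1000 TPM
    cols = {}
    for row in data.itertuples():
        noise = np.power(2.0, rng.normal(0, config.tpm_noise_sd, len(genes)))
        vals = base * noise
        cols[row.sample_id] = vals
    tpm = pd.DataFrame(cols, index=pd.Index(genes, name="gene"))
    tpm.loc["Actb"] = data.set_index("sample_id")["actb_tpm"]
    return tpm


# ----------------------------------------------------------------------
# cleavage angles and bisection circumferences
# ----------------------------------------------------------------------

@dataclass
class AngleSimConfig:
    """First-cleavage angle distribution per ICSI site.

    Polar injections (ipsilateral, contralateral) fall in the
    perpendicular 60-90 degree band with probability
    ``perpendicular_bias`` and uniformly in [0, 60) otherwise;
    equatorial injections cleave at any angle (uniform on [0, 90]).
    """

    n_per_group: int = 8
    groups: tuple[str, ...] = ("ipsilateral", "equatorial", "contralateral")
    perpendicular_bias: float = 0.7
    seed: int = 0

    def __post_init__(self):
        _require(self.n_per_group >= 1, "n_per_group", "must be >= 1")
        _require(0.0 <= self.perpendicular_bias <= 1.0,
                 "perpendicular_bias", "must lie in [0, 1]")


def generate_angles(config: AngleSimConfig) -> pd.DataFrame:
    """Simulate folded cleavage angles; columns zygote_id, icsi_site,
    angle_deg."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in config.groups:
        for i in range(config.n_per_group):
            if group == "equatorial":
                angle = rng.uniform(0.0, 90.0)
            else:
                if rng.random() < config.perpendicular_bias:
                    angle = rng.uniform(60.0, 90.0)
                else:
                    angle = rng.uniform(0.0, 60.0)
            rows.append(
                {"zygote_id": f"{group}_z{i + 1:02d}",
                 "icsi_site": group,
                 "angle_deg": angle}
            )
    return pd.DataFrame(rows)


@dataclass
class GeometrySimConfig:
    """Hemisphere circumference pairs for bisection-accuracy training.

    ``bisection_cv`` is the ln-scale SD of the volume-split factor, the
    same parametrization as :class:`ProteomeSimConfig`; the default
    reproduces a mean larger/smaller volume ratio of ~1.08.
    """

    n_pairs: int = 21
    mean_radius_um: float = 32.0
    radius_sd_um: float = 1.5
    bisection_cv: float = 0.093
    seed: int = 0

    def __post_init__(self):
        _require(self.n_pairs >= 1, "n_pairs", "must be >= 1")
        _require(self.mean_radius_um > 0, "mean_radius_um", "must be > 0")
        _require(self.radius_sd_um >= 0, "radius_sd_um", "must be >= 0")
        _require(self.bisection_cv >= 0, "bisection_cv", "must be >= 0")


def generate_circumference_pairs(config: GeometrySimConfig) -> pd.DataFrame:
    """Simulate sister-hemisphere circumference pairs (id, c1_um, c2_um)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_pairs):
        r0 = max(rng.normal(config.mean_radius_um, config.radius_sd_um), 1.0)
        v0 = 4.0 / 3.0 * math.pi * r0**3
        g = rng.normal(0, config.bisection_cv)
        v1, v2 = v0 * math.exp(g / 2.0), v0 * math.exp(-g / 2.0)
        c1, c2 = (
            2.0 * math.pi * (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0)
            for v in (v1, v2)
        )
        rows.append({"id": f"pair{i + 1:02d}", "c1_um": c1, "c2_um": c2})
    return pd.DataFrame(rows)
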