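"""Umbrella pipeline: simulate or load inputs, run every stage, summarize.

The pipeline chains the stages in dependency order — completeness filter
-> variance partition -> regionalized selection -> PCA resolution for
the proteome; a/b assignment -> paired statistics -> delta analysis for
the twins; volume ratios and angle-band fractions for the geometry —
and writes per-stage TSV outputs plus one JSON summary.  Given the same
configuration and seed the summary is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as oio
from . import twins as tw
from .containers import LINEAGES
from .geometry import bisection_summary, fold_angle, perpendicular_fraction
from .pca import assess_resolution, project
from .simulate import (
    AngleSimConfig,
    GeometrySimConfig,
    ProteomeSimConfig,
    TwinSimConfig,
    generate_angles,
    generate_circumference_pairs,
    generate_half_proteomes,
    generate_twin_pairs,
)
from .varpart import (
    compare_ratio_distributions,
    compare_sets,
    filter_complete,
    implied_fold,
    partition_variance,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

ALL_STAGES = ("proteome", "twins", "geometry")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Input paths are optional: a stage with no inputs simulates its data
    from ``seed``.  Thresholds default to the analysis conventions
    (SSwo/SS >= 0.80, TPM > 1 in >= 3 samples, perpendicular band
    60-90 degrees).
    """

    out_dir: str = "oosplit_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    ratio_threshold: float = 0.80
    log2: bool = True
    min_tpm: float = 1.0
    min_samples: int = 3
    band: tuple[float, float] = (60.0, 90.0)
    ab_key: str = "total_cells"
    proteome_matrix: str | None = None
    proteome_design: str | None = None
    pair_table: str | None = None
    tpm_matrix: str | None = None
    angles: str | None = None
    circumferences: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if not 0.0 <= self.ratio_threshold <= 1.0:
            raise ValueError("ratio_threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        if "band" in kwargs:
            kwargs["band"] = tuple(kwargs["band"])
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)


def _proteome_stage(config: RunConfig, out: Path) -> dict:
    datasets = {}
    if config.proteome_matrix:
        matrix = oio.read_proteome(config.proteome_matrix, config.proteome_design)
        datasets[matrix.axis] = (matrix, None)
    else:
        for i, axis in enumerate(("equatorial", "meridional")):
            sim = ProteomeSimConfig(axis=axis, seed=config.seed + i)
            datasets[axis] = generate_half_proteomes(sim)
    summary: dict = {"threshold": config.ratio_threshold,
                     "implied_fold": implied_fold(config.ratio_threshold)}
    results = {}
    selections = {}
    for axis, (matrix, truth) in datasets.items():
        complete = filter_complete(matrix)
        res = partition_variance(complete, log2=config.log2)
        selected = res.select(config.ratio_threshold)
        scores = project(complete, selected, log2=config.log2) if selected else None
        resolved, silhouette = False, None
        if scores is not None:
            rep = assess_resolution(scores, complete.hemisphere_of,
                                    n_proteins=len(selected))
            resolved, silhouette = rep.separable, rep.separation_score
        oio.write_proteome(matrix, out / f"proteome_{axis}_matrix.tsv",
                           out / f"proteome_{axis}_design.tsv")
        res.table.rename_axis("protein_id").to_csv(
            out / f"varpart_{axis}.tsv", sep="\t", na_rep=oio.NA_REP)
        (out / f"selected_{axis}.txt").write_text(
            "".join(f"{p}\n" for p in selected))
        results[axis] = res
        selections[axis] = selected
        axis_summary = {
            "n_proteins": matrix.n_proteins,
            "n_complete": complete.n_proteins,
            "n_selected": len(selected),
            "resolved": resolved,
            "silhouette": silhouette,
        }
        if truth is not None:
            hits = len(set(selected) & truth)
            axis_summary["truth_proteins"] = len(truth)
            axis_summary["sensitivity"] = hits / len(truth) if truth else None
            axis_summary["false_positive_fraction"] = (
                (len(selected) - hits) / len(selected) if selected else None
            )
        summary[axis] = axis_summary
    if len(results) == 2:
        venn = compare_sets(selections["equatorial"], selections["meridional"])
        corr = compare_ratio_distributions(results["equatorial"],
                                           results["meridional"])
        summary["venn"] = {"only_equatorial": venn.only_a,
                           "only_meridional": venn.only_b,
                           "overlap": venn.overlap,
                           "unique_total": venn.unique_total}
        summary["ratio_spearman"] = {"rho": corr.rho, "p": corr.pvalue,
                                     "n_shared": corr.n}
    return summary


def _twins_stage(config: RunConfig, out: Path) -> dict:
    if config.pair_table:
        table = oio.read_pair_table(config.pair_table, config.tpm_matrix)
    else:
        table = generate_twin_pairs(TwinSimConfig(seed=config.seed))
    table = tw.assign_ab(table, key=config.ab_key)
    oio.write_pair_table(table, out / "twin_pairs.tsv")
    summary: dict = {"n_pairs": int(table.n_pairs), "ab_key": config.ab_key}
    for group in sorted(map(str, table.groups)):
        gsum: dict = {}
        for lineage in LINEAGES:
            corr = tw.paired_correlation(table, lineage, group)
            loc = tw.paired_location_test(table, lineage, group)
            gsum[lineage] = {"rho": corr.rho, "rho_p": corr.pvalue,
                             "wilcoxon_p": loc.pvalue, "n": corr.n}
        deltas = tw.delta_analysis(table, group=group)
        gsum["delta_epiblast_at_equal_totals"] = (
            deltas.restricted_mean["epiblast"])
        gsum["n_equal_total_pairs"] = deltas.n_restricted
        summary[group] = gsum
    if table.tpm is not None:
        filtered = tw.filter_tpm(table.tpm, config.min_tpm, config.min_samples)
        ranked = tw.rank_absolute_differences(table)
        ranked.to_csv(out / "ranked_abs_tpm_diff.tsv", sep="\t",
                      header=True)
        oio.write_tpm(filtered, out / "tpm_filtered.tsv")
        summary["tpm"] = {"n_genes": int(table.tpm.shape[0]),
                          "n_genes_filtered": int(filtered.shape[0])}
    return summary


def _geometry_stage(config: RunConfig, out: Path) -> dict:
    if config.angles:
        angles = oio.read_angles(config.angles)
    else:
        angles = generate_angles(AngleSimConfig(seed=config.seed))
    angles = angles.assign(angle_deg=[fold_angle(a) for a in angles["angle_deg"]])
    if config.circumferences:
        pairs = oio.read_circumferences(config.circumferences)
    else:
        pairs = generate_circumference_pairs(GeometrySimConfig(seed=config.seed))
    oio.write_angles(angles, out / "angles.tsv")
    oio.write_circumferences(pairs, out / "circumferences.tsv")
    fractions = perpendicular_fraction(
        angles, band=config.band,
        pool=("ipsilateral", "contralateral")
        if {"ipsilateral", "contralateral"} <= set(angles["icsi_site"]) else None,
    )
    return {"band": list(config.band),
            "perpendicular_fraction": fractions,
            "bisection": bisection_summary(pairs)}


_STAGE_FUNCS = {
    "proteome": _proteome_stage,
    "twins": _twins_stage,
    "geometry": _geometry_stage,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages; return (and write) the JSON summary.

    On a stage failure the outputs of completed stages and a manifest
    are preserved before the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"schema_version": SCHEMA_VERSION, "seed": config.seed}
    completed: list[str] = []
    try:
        for stage in config.stages:
            logger.info("running stage %s", stage)
            summary[stage] = _STAGE_FUNCS[stage](config, out)
            completed.append(stage)
    finally:
        manifest = {"completed_stages": completed,
                    "requested_stages": list(config.stages)}
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        (out / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
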