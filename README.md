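# oosplit

Statistical tooling for asking whether the mouse oocyte's cytoplasm is
regionalized, and whether that regionalization leaves a trace in the
embryo.  The package serves developmental biologists working with
half-cell proteomics of bisected oocytes, twin blastocysts derived from
split 2-cell embryos, and micromanipulation geometry (bisection
accuracy, first-cleavage angles).

## What it computes

**Within/between-oocyte variance partition.**  For each protein
measured in all 2N hemispheres of N bisected oocytes, the total sum of
squares about the grand mean is decomposed as in a one-way ANOVA with
oocytes as groups and the two hemispheres as replicates:

    SS = Σ_{o,h} (x_{o,h} − x̄)²,   SSbo = Σ_o 2(x̄_o − x̄)²,   SSwo = SS − SSbo

The ratio SSwo/SS ∈ [0, 1] is 1 when hemisphere differences dominate
and 0 when oocyte-to-oocyte differences dominate; proteins with
SSwo/SS ≥ 0.80 (within-oocyte variation ≥ 4× between-oocyte) are
flagged as regionalized, and the selected submatrix is tested for
hemisphere resolution by PCA with an exact linear-separability check
plus a silhouette score.

**Paired twin statistics.**  Twin blastocyst pairs are ordered by a
size proxy (twin 'a' = lower total cell count, or lower *Actb* TPM for
transcriptome data), then compared with Spearman correlations (exact
permutation p for n ≤ 9), Wilcoxon signed-rank tests (exact null for
n ≤ 25), and a delta-vs-delta analysis that measures the lineage
imbalance |epi_a − epi_b| among pairs whose *total* cell numbers are
equal.  TPM utilities implement gene filtering (TPM > 1 in ≥ 3
samples, geometric-mean ordering), joint pair dropping, ranked
absolute-difference export for enrichment tools, and group-normalized
expression ratios.

**Geometry.**  Hemisphere volumetrics from circumferences
(V = c³/6π², larger/smaller volume ratio, percent difference) and
cleavage-angle analysis (folding into [0°, 90°], fraction in the
perpendicular 60–90° band per injection site).

A synthetic-data module (`oosplit.simulate`) generates half-proteome
matrices, twin-pair tables, angle tables and circumference pairs with
the statistical structure above, so the whole pipeline is testable
without any external data.

## Worked example

```python
import oosplit as oo

matrix, truth = oo.generate_half_proteomes(oo.ProteomeSimConfig(seed=7))
complete = oo.filter_complete(matrix)
results = oo.VariancePartition(complete, log2=True).fit()
print(results.summary())

selected = results.select(0.80)
scores = oo.project(complete, selected, log2=True)
report = oo.assess_resolution(scores, complete.hemisphere_of,
                              n_proteins=len(selected))
print(report.summary())
```

prints

```
Within/between-oocyte variance partition
============================================
axis:                  equatorial
scale:                 log2
oocytes:               6
proteins:              746
ratio defined:         746
median SSwo/SS:        0.1264
ratio >= 0.80:          35
implied within/between fold at 0.80: 4.0

PCA hemisphere resolution
================================
proteins used:     35
halves:            12
classes:           ['A', 'V']
resolved:          True
resolving axis:    PC1
mean silhouette:   0.8465
```

Of the 1400 simulated proteins, 746 are detected in all 12 hemispheres;
35 exceed the 0.80 ratio threshold, and that subset cleanly separates
animal from vegetal halves on PC1 (silhouette 0.85).  The twin side
works the same way:

```python
twins = oo.generate_twin_pairs(oo.TwinSimConfig(seed=7))
model = oo.TwinPairModel(twins)           # orders pairs by total cells
print(model.fit("epiblast", group="equatorial").summary())
```

```
Paired twin-cotwin analysis: epiblast [equatorial]
============================================
complete pairs:        20
Spearman rho (a vs b): -0.3228 (p = 0.1651)
Wilcoxon signed-rank:  W = 61.5, p = 0.3247 (2 zero difference(s) dropped)
mean |delta epiblast| at matched totals: 2.00 (n = 3)
```

Three of the 20 equatorial pairs have identical total cell counts, yet
their epiblasts still differ by 2 cells on average — the imbalance is
not a by-product of unequal proliferation.  Finally, the geometry:

```python
geom = oo.hemisphere_ratio(150.0, 150.0 * 1.079 ** (1/3))
print(f"volume ratio {geom.ratio:.3f} -> percent difference {geom.percent_diff:.1f}%")
# volume ratio 1.079 -> percent difference 7.9%
```

## Command line

```sh
oosplit simulate --kind proteome --seed 3 --out sim/
oosplit partition --matrix sim/matrix.tsv --design sim/design.tsv --log2 --out out/
oosplit resolve --matrix sim/matrix.tsv --design sim/design.tsv --log2 \
        --plot out/pca.svg --out out/
oosplit twins --pairs pairs.tsv --out out/
oosplit geometry --angles angles.tsv --circumferences circ.tsv --out out/
oosplit run --seed 1 --out full_run/      # all stages, JSON summary
```

All tabular I/O is TSV (missing values as `NA`, distinct from zero);
summaries are JSON; plots are SVG.

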