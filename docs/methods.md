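# Methods

## Scientific setting

A mouse metaphase-II (MII) oocyte is not a homogeneous bag of cytoplasm.
If its proteome is regionalized — some proteins more abundant in one
hemisphere than the other — then the orientation of the first zygotic
cleavage decides how those proteins are apportioned to the two
blastomeres, and downstream the two twin blastocysts derived from split
2-cell embryos can differ in epiblast cell number ("epiblast
imbalance").  `oosplit` implements the three quantitative layers of that
argument: (i) a per-protein variance decomposition of half-oocyte LFQ
matrices that detects regionalization without knowing which hemisphere
is which, (ii) paired twin/cotwin statistics on blastocyst lineage
counts, ES-colony counts and TPM matrices, and (iii) the geometry of
bisection accuracy and first-cleavage angles.

## Variance partition (`oosplit.varpart`)

For protein *p* measured in all 2N hemispheres (two per oocyte), with
x_{o,h} the abundance in hemisphere *h* of oocyte *o* and x̄ the grand
mean:

    SS    = Σ_{o,h} (x_{o,h} − x̄)²
    SSbo  = Σ_o 2 (x̄_o − x̄)²           (x̄_o: mean of the two halves)
    SSwo  = SS − SSbo = Σ_o Σ_h (x_{o,h} − x̄_o)²

This is the one-way ANOVA decomposition with oocytes as groups and
hemispheres as replicates.  The between-oocyte term uses per-oocyte
*means with multiplicity two* rather than per-oocyte sums: sums would
break the guarantee SSwo = SS − SSbo ≥ 0, which the ratio depends on.
The statistic SSwo/SS ∈ [0, 1] reads 1 when hemisphere differences
dominate and 0 when oocyte-to-oocyte differences dominate.  A selection
threshold *t* on the ratio corresponds to demanding within-oocyte
variation t/(1−t) times the between-oocyte variation (4× at t = 0.80).
The decomposition is label-free: it needs to know which halves belong
together, not which half is A or V — the property that makes it usable
for meridional bisections whose L/R labels are arbitrary.  It is also
relatively insensitive to the bisection volume error, which scales all
proteins of one half jointly and adds a shared, small within-oocyte
component rather than protein-specific signal.

Numerical details: SSwo is clipped at 0 against round-off; proteins
with SS = 0 get an undefined (NaN) ratio, are flagged, and are excluded
from ranking; the decomposition identity is tested at relative 1e-9.
Selection at the threshold is inclusive (≥, configurable), sorted by
ratio descending with ties broken by protein identifier.  The analysis
runs on abundances as provided, with an optional log2 pre-transform
(`log2=True`); the worked examples and downstream simulation harnesses
use the log2 scale, the natural scale for multiplicative LFQ data.

## PCA resolution (`oosplit.pca`)

Whether a selected protein set "resolves" the hemisphere classes is
operationalized as perfect linear separability of the two classes in
the PCA of the per-protein standardized submatrix: PC1 alone, PC2
alone (strict gap between class ranges), or the PC1–PC2 plane, where
separability is decided exactly by a linear-programming feasibility
test (∃ w, b with y_i(w·x_i + b) ≥ 1).  Two components are inspected.
The mean silhouette width on the PC1–PC2 plane is reported as a graded
separation score (positive under separation, but silhouette alone does
not define "resolved").  The threshold scan evaluates a descending grid
(0.95 → 0.50, step 0.05) and returns the lowest threshold whose
selection still resolves, with a per-threshold report; empty selections
are marked unresolvable and skipped.

## Twin-pair analyses (`oosplit.twins`)

*a/b ordering.*  The member of each pair with the lower ordering key is
twin 'a': total cell count for imaging data, *Actb* TPM for
transcriptome data (*Actb* mRNA scales with cell number).  Ties are
broken by sample identifier and logged.  The ordering is idempotent and
invariant to input row order.

*Paired statistics.*  Spearman's ρ of a-values vs b-values across
pairs, with an exact permutation p-value for n ≤ 9 (all n!
permutations, average ranks for ties) and the t approximation above.
The Wilcoxon signed-rank test drops zero differences (count reported;
all-zero gives p = 1 with a warning), uses the exact null for n ≤ 25
and the normal approximation with continuity correction above.

*Delta analysis.*  Per pair, Δ = |a − b| for the total and for each
lineage (epiblast, primitive endoderm, trophectoderm); Spearman ρ of
Δ_lineage vs Δ_total per lineage; and the mean (and range, since "two
to three cells" may be read either way) of Δ_lineage restricted to
pairs with Δ_total = 0.  The restriction is exact by default with a
configurable window (`window=1` keeps |Δ_total| ≤ 1).

*TPM utilities.*  Genes are retained when TPM > 1 (strict) in at least
3 samples, then sorted by geometric mean TPM descending; a retained
gene that still contains zeros uses the geometric mean of its positive
values (logged).  Pair completeness is enforced jointly (discarding a
twin discards the cotwin).  The unsupervised export ranks genes by the
mean absolute twin-cotwin TPM difference, descending, ties by symbol —
this ordering is what enrichment tools consume; enrichment itself is
out of scope.  Group expression ratios divide per-gene group means by a
reference group (ratio ≡ 1 for the reference).  Marker panels for the
three lineages and housekeeping genes ship as editable text files.

## Geometry (`oosplit.geometry`)

Each half is treated as a sphere measured by its own circumference:
r = c/2π, V = 4/3·π·r³ = c³/(6π²).  Bisection accuracy is the
larger/smaller volume ratio (≥ 1; exactly the cubed circumference
ratio) and its percent difference.  Cleavage angles are folded into
[0°, 90°] (mod 180°, then supplement above 90°); the perpendicular band
is [60°, 90°] with both endpoints inclusive — the lower endpoint is a
convention, and fractions at a 60.0° datum are sensitive to it.

## Synthetic data (`oosplit.simulate`)

The generators define the study conditions used throughout the tests.

*Half proteomes.*  log2 abundance = per-protein baseline
N(20, 2.5²) + per-(protein, oocyte) offset N(0, σ_b²) + per-half noise
N(0, σ_n²) + hemisphere effect (regionalized subset only) + volume
factor.  Defaults: 6 oocytes, 1400 proteins, 5% regionalized
(exactly round(0.05·1400) = 70), σ_b = 0.3, σ_n = 0.1, effect = 1.5,
missingness 5% completely at random (NaN, never 0).  The volume factor
models the bisection error: one draw g ~ N(0, cv) per oocyte scales the
halves by e^{±g/2}, so the larger/smaller volume ratio is e^{|g|}; the
default cv = 0.093 solves E[e^{|g|}] − 1 = 7.9%, the observed mean
volume excess (implied SD ≈ 5.6%).  Equatorial simulations put the
effect on the A half of every oocyte; meridional simulations put it on
a random side per oocyte, because the L/R labels are an arbitrary
convention relative to any real intracellular gradient — this is what
makes simulated L/R classes unresolvable in PCA even though the same
proteins pass the ratio threshold.  A log-normal abundance model and
MCAR missingness are stand-ins: real LFQ data have intensity-dependent
dropout and correlated batch structure that the generator does not
emulate, so passing recovery tests demonstrate correctness of the
machinery under the assumed model, not performance on real spectra.

*Twin pairs.*  Per pair: pair-level total ~ N(50, 5²) split with a
within-pair difference N(0, 3²); epiblast midpoint N(5, 1²) split by a
half-normal difference with mean equal to the group's configured
imbalance (default 2.5 cells equatorial, 2.0 polar) and random sign,
independent of the total-cell difference; primitive endoderm ~ N(8,
0.8²) balanced; trophectoderm absorbs the remainder; ES colonies ~
Binomial(epiblast, 0.7); counts are rounded and clamped at 0 (logged).
The TPM matrix gives every sample per-gene log-normal levels with
0.25 log2-SD sample noise, except *Actb* = 100 TPM/cell × total cells
(±5%), so *Actb* — and only *Actb* — tracks cell number, mirroring the
finding that lineage transcripts do not expose the count imbalance.

*Angles / circumferences.*  Polar-injection zygotes cleave in the
60–90° band with probability 0.7 (else uniform [0°, 60°)); equatorial
zygotes uniform on [0°, 90°].  Circumference pairs derive from a base
radius N(32, 1.5²) µm split by the same volume-factor model.

## Problem sizes and harnesses

Parameter-recovery and resolution checks run 20 seeds at the full
study scale (1400 × 12 matrices), which completes in seconds; null
calibration of the signed-rank test uses 1000 simulated tables of 20
pairs.  The recovery harness uses hemisphere effect 2.0, noise 0.1 and
volume cv 0.05 (effect ≥ 2·noise, small bisection error), and measures
sensitivity against truth proteins present after the completeness
filter.  The delta-recovery harness uses 40 pairs per group so that
pairs with Δ_total = 0 accumulate to ~100 across seeds.  The
`scripts/acceptance.py` entry point recomputes the desk-scale constants
and all simulation quantities from scratch with a user seed.

## Known limitations

No enrichment or GO semantics; no raw spectra, reads or image
processing; readers accept pre-downloaded supplementary-style TSVs via
column conventions but no remote fetching.  The linear-separability
criterion with 6 halves per class is permissive (few points in 2-D
separate easily); it is therefore always paired with the silhouette
score, and simulated null (L/R) datasets calibrate its false-positive
behavior.  Exact Spearman permutation is limited to n ≤ 9 by
factorial growth.
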