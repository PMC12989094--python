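# Methods

This note records the models, defaults and design choices behind
`namscan`, and what the simulation-based tests do and do not establish.

## Genotype simulator

Each NAM family is an independent BC1S3 pedigree: an F1 between the elite
recurrent parent and the family's wild donor is backcrossed once to the
elite parent, and the product selfed for three generations; every line
realises its own gamete chain. Meiosis uses the **Haldane map function**
(no crossover interference), `r = (1 - exp(-2d/100))/2` for d in cM —
the simplest standard choice. Marker cM positions are proportional to
physical position; default chromosome set is the seven barley chromosomes
(~516–665 Mbp, 126–165 cM).

The single-locus dosage law is then exactly
`P(0,1,2) = (23/32, 1/16, 7/32)` with mean 1/2 and heterozygosity 1/16 ≈
6.25% — comfortably inside the <12.5%-heterozygosity QC retention rule,
which is why simulated markers survive QC.

Defaults are the screening-study conditions: 25 families x 16 lines
(400 lines), 2 treatments (C/S), 4 replicates, 300 markers/chromosome.
Each family's donor carries the wild allele at every marker by default
(`donor_allele_freq = 1.0`), keeping the genotype law exact per marker;
lowering it creates family-monomorphic markers for QC testing. Missing
calls are injected at a configurable rate (default 0).

What the simulator does **not** model: sequence-level variation, real
(non-uniform) recombination maps, crossover interference, segregation
distortion, and the DNA pooling of several plants per line (a pooled
sample would inflate apparent heterozygosity; we model one consensus
genotype per line).

## Phenotype generator

`Y_ijk = mu_j + fam + QTL + g_i + (gt)_ij + r_k(j) + e_ijk`, with
`mu_S = factor x mu_C` per trait. Stress factors default to the
seedling-seawater presets (SL 0.305, RL 0.316, CL 0.849, FW 0.429, DW and
germination ~1), so mean reductions emulate ~70% shoot/root shortening
under ~40% seawater. Variance components (trait units²) default to
per-trait values sized so line-mean heritabilities land in the realistic
0.7–0.9 band (e.g. SL: σg²=1.0, σgt²=0.25, σrep²=0.1, σe²=0.5 on a 10 cm
mean). Germination is generated as a latent normal rounded and clipped to
a seed count in [0, 16]; FW/DW pairs are nudged to keep FW > DW > 0 so
water-content and dry-matter ratios are always defined.

`plant_qtls` sizes additive effects so each QTL explains a requested
fraction of the *within-treatment line-mean* response variance (the
variance the GWAS actually sees), accounting for the variance the planted
QTLs themselves add.

## Derived traits and tolerance indices

Replicate means per (line, treatment) require ≥ 2 non-missing replicates;
below that the cell is missing. TIs divide line-level treatment means
(not replicate-paired values). Zero denominators (FW, SL or control mean
= 0) yield missing values with a logged warning, never exceptions.
`WCP + 100·(DW/FW) = 100` holds exactly by construction — the idealised
limit of the strong negative WCP vs DW/FW correlation seen in real data.

## Variance components, H², BLUEs

Components come from **expected mean squares** of the balanced two-way
ANOVA (genotype random, treatment fixed, replicate nested in treatment),
truncated at zero. For balanced data with interior solutions these equal
REML — verified in the test suite against an independent lme4 fit. Truly
unbalanced designs (a genotype absent from a treatment) raise an error
naming the offenders rather than silently dropping cells.

H² uses the line-mean basis `σg²/(σg² + σgt²/y + σe²/(yr))`, clamped to
[0, 1]; this parenthesisation is a deliberate choice where the printed
formula in common write-ups is typographically ambiguous.

BLUEs solve the GLS normal equations with replicate the only random term;
the replicate and residual variances come from within-treatment EMS and
the n x n solve uses the Woodbury identity (replicate count is small). On
balanced data the BLUE equals the genotype mean exactly — an algebraic
property the tests assert at 1e-8.

Whether GWAS responses are BLUEs or raw line means is configurable in the
CLI (`--responses blues|means`); BLUEs are the default.

## LD decay

r² is the squared Pearson correlation of dosage columns over lines
(pairwise-complete across missing calls), intrachromosomal pairs only.
The decay curve is a LOESS fit (span 0.3) of r² on physical distance,
fitted on pairs within 50 Mbp by default — long-range pairs carry no
decay information and destabilise a local smoother — with pairs
subsampled to 200,000 per chromosome (seeded) for tractability. The decay
distance is the first grid point whose fit drops below the threshold
(default r² = 0.2); a never-crossing fit returns a sentinel, which is the
expected outcome *within* the 50-Mbp cap for a BC1S3 panel, where only ~8
meioses separate lines and LD extends over tens of cM.

## Three-step scan

Step I draws `n_subsamples` (default 100) random 80/20 splits (optionally
stratified by family; default unstratified). Within a split, forward
selection on the training lines picks at each step the marker with the
largest training-RSS reduction (computed by Gram–Schmidt residualisation,
O(np) per step) and keeps it only while the held-out mean squared
prediction error decreases; the path stops at the first increase. Markers
kept in ≥ `min_selection_count` (default 2, "selected more than once")
splits become candidates. A min-over-path stopping variant was measured
and gave essentially identical selection counts.

Step II runs greedy forward selection over the candidates on the full
data, minimising `SBC = n ln(RSS/n) + k ln(n)` with k counting all model
parameters (intercept included); additions that leave the design
rank-deficient are skipped with a log note; the search stops at the first
non-improving step or at `max_cofactors` (default 20).

Step III fits `y ~ 1 + cofactors + m` for every marker m; the p-value is
the two-sided t-test of m entered last (equal to the sequential type-I
test of the final term), `sp_r2` is its incremental R² over the cofactor
model relative to the total sum of squares, and the dosage coefficient is
the allele effect (positive = wild allele raises the trait). Cofactors
correlated with m at |r| ≥ 0.99 — m itself included — are dropped from
m's own background, so each cofactor is tested on its marginal signal.
Missing dosages are mean-imputed per marker (fraction logged); markers
monomorphic after residualisation get p = 1 and zero effect. LOD is
`-log10(p)` and the genome-wide threshold is Bonferroni,
`-log10(alpha/n_tests)`.

No kinship/relatedness matrix is used: in a NAM panel the recurrent
parent removes most stratification and background control is delegated to
the cofactors, mirroring the multiple-linear-regression design this
package implements. The dosage matrix itself is the identity-by-state
predictor set.

## QTL calling and genes

Significant markers merge per trait and chromosome: peaks are taken in
descending LOD order, suppressing further significant markers within one
window width (default 1.7 Mbp, read as ±0.85 Mbp — the "window
surrounding" phrasing is ambiguous and the width is configurable).
Identifiers are `Q_<marker-suffix>_<chrom>-<ordinal>` with ordinals
assigned per chromosome in position order **across traits**, so a peak
shared by several traits keeps one identifier; co-localisation groups by
shared peak marker (default) or overlapping windows. Gene windows are
half-open `[pos − w/2, pos + w/2)` against 1-based inclusive gene
coordinates: a gene ending exactly at the window start is excluded.

## Numerical choices and degenerate inputs

Dosage columns with near-zero residual variance are excluded from
selection scores (threshold 1e-10 relative); RSS is floored at 1e-300
inside the SBC logarithm; p-values are clipped to the smallest positive
float so LOD is always finite; variance components truncate at zero.
Zero-variance responses and traits with > 20% missing lines are skipped
with a warning in batch runs, and raise informative errors when called
directly.

## Problem sizes used in tests and the acceptance script

Simulation-backed checks run at deliberately compact sizes chosen to keep
Monte-Carlo error well below the tested tolerances: the genotype law at
10,000 lines, heritability recovery over 50 (tests) or 20 (script)
replicate experiments of 400 genotypes, null-scan uniformity over 50
scans of 200 lines x 40 independent markers, and the power study on the
full 400-line, 2,000-marker panel over 20 seeded replicates.

## Known limitations

* Localisation resolution: in a BC1S3 panel at n = 400 with ~0.5 cM
  marker spacing, adjacent-marker dosage correlation is ≈ 0.98. For a QTL
  explaining ~10% of the response variance, the sampling noise of
  marker–response correlations exceeds the correlation gap between the
  causal marker and neighbours several cM away, so cofactor selection
  regularly lands on a close *shadow* of the truth, and the shadow —
  tested on its marginal signal — carries the peak. The power study in
  the acceptance suite quantifies this: expecting 1-cM localisation of
  10%-variance QTLs in ≥ 18/20 runs is beyond what the data support
  (measured ≈ 4/20 for full within-1-cM detection), and a diagnostic
  comparison shows the shadow model can attain *lower* SBC than the
  true-marker model, i.e. no SBC-consistent selector could do better.
  Candidate windows (1.7 Mbp) should therefore be read as lower bounds on
  positional uncertainty at small effect sizes.
* EMS variance components require balanced data; unbalanced designs need
  an external REML fit.
* The scan assumes additive dosage effects; dominance and family-specific
  allele series are not modelled.
* Passing tests on simulated panels shows the statistical machinery is
  correct under the generative model; it does not certify performance on
  real chip data with non-uniform recombination, segregation distortion
  or shared non-genetic structure.
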