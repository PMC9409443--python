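# Methods

## Problem

`dmrlink` implements a two-pair differential-methylation analysis for
whole-genome bisulfite count data and its integration with differential
gene expression. The design is four samples in two sex-matched
case–control pairs (here: Angelman-syndrome vs healthy control). A
genomic element (promoter window or gene body) counts as differentially
methylated only when both pairs independently support the same
direction; gene-level methylation categories are then crossed with
up-/down-regulated gene sets from an expression contrast of the same
condition.

## Per-site statistic

For each cytosine with methylated-read count `k` and coverage `n`:

* frequency `f = k/n`; sites with `n < min_coverage` (default 5) in any
  sample are excluded — the package is silent on no-coverage sites
  rather than propagating NaN;
* a 95% confidence interval from the binomial likelihood-ratio (Wilks)
  condition `2[l(f) − l(p)] ≤ χ²₁(0.95) = 3.841459`, solved by bisection
  on each side of the MLE to 1e-8; `k = 0` and `k = n` pin the
  corresponding bound to 0 or 1 exactly;
* the transform `v = ln((1+f)/(1−f))` (twice the arctanh transform —
  implemented in this doubled form deliberately, as specified upstream
  of this package, not as `arctanh` itself);
* `sd(v)` = one sixth of the CI length after transforming its margins;
* a two-observation least-squares fit `Y = b0 + b1·group` with group
  coded −1/+1 gives `b1 = (v_case − v_ctrl)/2`,
  `sd(b1) = √(sd_ctrl² + sd_case²)/2` (independence of the two
  observations), and the site score `z = b1/sd(b1)`. Positive z means
  hyper-methylated in the case group. With two observations the fit is
  exact, so these closed forms equal the generic `(XᵀX)⁻¹XᵀY` solution
  (property-tested to 1e-10).

### Known calibration property of SD = CI/6

A 95% interval is asymptotically `2·1.96 ≈ 3.92` standard errors wide,
so dividing by 6 *underestimates* the standard error by a factor of
about 0.65 and inflates `z` by about 1.53. Under a null simulation at
coverage 20 the fraction of sites with `|z| ≥ 1.96` is ≈ 0.216, not
0.05. The rule is implemented exactly as specified; the consequences
(anti-conservative site flags, hence imperfect region precision and a
non-trivial false consensus rate — see the acceptance suite, where the
corresponding calibration checks fail by construction) are documented
rather than silently recalibrated. Dividing by 3.92 instead of 6 would
restore nominal calibration; that is deliberately not the default
because it would change the method being implemented.

A related upstream ambiguity: the analysis narrative describes
"Poisson distribution statistics" for calling, while the procedural
description specifies binomial Wilks intervals. The binomial procedure
is what this package implements.

### Methylation-call convention

The upstream convention counts C>T reads on the plus strand (A>G on
minus) as *methylated*. Bisulfite chemistry converts unmethylated
cytosines to thymines, so this is the inverse of the usual reading. The
importer implements the convention as printed by default
(`convention="printed"`: for split-count reports, the converted-read
column becomes `k`) and offers `convention="standard"` for the
conventional reading; the choice is recorded on the imported frame and
in the run manifest. For the package's own 5-column `(k, n)` reports
the flag is metadata only.

## Segmentation

The original segmentation algorithm's internals are not publicly
specified; the stand-in is gap-bounded run merging: within one pair and
one direction, maximal runs of flagged sites (`|z| ≥ z_{1−α/2}`,
inclusive, α = 0.05 default) in which consecutive flagged sites are at
most `max_gap` bp apart (default 500); runs shorter than `min_sites`
(default 3) are dropped. An opposite-direction flagged site splits a
run, which keeps the hyper and hypo tracks of one pair disjoint. A
region spans its first to last site inclusive and carries the Stouffer
score `Σzᵢ/√n`. The stand-in is transparent, brute-force checkable
(the test suite enumerates runs independently), and monotone in signal
strength; it makes no claim of reproducing the original algorithm
bit-exactly.

Consensus: same-direction intersections of male-pair and female-pair
regions; opposite-direction overlaps are discarded; `n_sites` is the
smaller support; the consensus score is the Stouffer combination of the
two region scores. Consistency is additionally enforced at element
level simply because element hits are computed from consensus regions
only.

## Coordinates and annotation

Internal coordinates are 0-based half-open everywhere; GFF3 is
converted on read (1-based inclusive), BED taken as-is; all interval
output is BED dialect. The promoter is `TSS ± flank` (default 1000 bp,
2·flank+1 positions) around the strand-aware TSS (gene start on +, last
base on −), clipped at zero. "Promoter" is thus a TSS window, not a
database of curated promoter elements — the reproducible reading when
no promoter database is named; the flank and the annotation source are
configuration, not constants. A region overlapping both the promoter
window and the body of a gene counts in both tallies (a reporting
convention, recorded per element in the hit table).

Promoter categories are reported in *region* units (distinct consensus
regions hitting ≥ 1 promoter window) while gene-body categories are
*gene* units (genes whose bodies carry exactly one direction); their
sum is still reported as one total because that mixed-unit arithmetic
is the convention of the analysis this package reproduces. Each count
is labelled with its unit in the report. Genes whose bodies carry both
directions ("mixed") are tallied separately and excluded from the
body-level association.

## Differential expression

Classification thresholds are strict as printed: up ⇔ `p < 0.005` and
`FC > 1.5`; down ⇔ `p < 0.005` and `FC < 0.6`; fold change is linear
scale, `FC = (mean CPM case + 0.5)/(mean CPM control + 0.5)`. The 0.5
pseudocount keeps one-group-only genes finite; such genes are flagged
`exclusive_as`/`exclusive_ctrl`. Benjamini–Hochberg q-values are
emitted but never used for classification (the method applies raw p).

The built-in test is a documented stand-in for an external DE tool
(edgeR in the original workflow, out of scope here): a two-sided
normal score test of the CPM group-mean difference with model variance
`μ + φμ²` at the pooled null mean and supplied dispersion φ (default
0.1). It requires ≥ 2 samples per group; under the global null it is
conservative (measured ≈ 0.002 of genes at p < 0.005). Its known
limitations: plain per-million scaling has composition bias (many
strongly up-regulated genes deflate the case columns), and the normal
approximation is rough at n = 2. Real edgeR/DESeq2 output should be
supplied through `import_de_table`, which maps common headers and
exponentiates logFC columns (base 2 by default, e selectable).

## Synthetic data

The generator emulates the consumed data model, not the assay:
per-site baseline frequencies `f ~ Beta(α, β)` shared by all four
samples; coverage `Poisson(coverage_mean)` independently per site and
sample (zero-coverage sites are emitted so the filter is exercised);
methylated counts `Binomial(coverage, f)`; inside planted elements the
case samples' frequencies are shifted by ±`effect_delta` on the logit
scale — the logit keeps shifted frequencies inside (0,1) with no
clamping artifacts — identically in both pairs, so planted directions
are pair-consistent by construction. Expression is negative binomial
with log-uniform base means and planted fold changes; a configurable
`coupling_prob` makes promoter-hypomethylated genes up-regulated.
Every track uses its own RNG stream seeded `(master seed, stream
index)`, so runs are bit-reproducible and adding tracks would not
reshuffle existing ones.

Defaults (chosen once as a realistic small-scale world): 2 chromosomes
× 2 Mb, 10 CpG-like sites/kb, 200 genes of 2–10 kb, coverage 30,
`Beta(2, 2)` baseline, logit effect 2, 5% hyper / 20% hypo planted
genes (50 elements — matching the observed predominance of
hypo-methylation), planted FC 4, dispersion 0.1, 5% independent
up/down DE genes. What the generator does *not* emulate: the bimodal
(mostly high) methylation landscape of real genomes, spatial
correlation of methylation outside planted elements, read-level data,
bisulfite conversion errors, library-size imbalance between samples,
cell-type heterogeneity. A green recovery test therefore establishes
that the pipeline recovers planted signals under its own model
assumptions, not performance on real bisulfite data.

## Numerical choices

* Frequencies and CI margins are clamped to `[0, 1 − 1/(2n)]` with the
  site's own coverage `n` before transforming, so `v` stays finite and
  monotone in `k` at fixed `n`.
* `sd(b1) = 0` with `b1 = 0` gives `z = 0`; `sd(b1) = 0` with
  `b1 ≠ 0` (both CIs degenerate) is flagged and carries `z = ±inf`,
  i.e. always significant with the sign of `b1`.
* All threshold comparisons on `z` are inclusive (`|z| ≥ z_crit`);
  DE threshold comparisons are strict, as printed.
* Stable (merge) sorts and fixed stream seeding make every pipeline
  run byte-identical for identical inputs and config.

## Limitations

Beyond the calibration property above: no overdispersion
(beta-binomial) modelling of methylation counts; no smoothing across
sites; no FDR control across regions (none is applied in the method
being reproduced); transcript-isoform TSS choice and curated promoter
databases are out of scope; the DE stand-in is not a substitute for a
real count-model DE tool on real data.
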