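# dmrlink

Differential-methylation region calling from whole-genome bisulfite
count data in **two sex-matched case–control pairs**, and integration of
the resulting gene-level methylation categories with differential gene
expression. The package was built around the analysis design used for
Angelman syndrome (AS) patient data — two AS vs two control bisulfite
methylomes, two AS vs two control RNA-seq neuron samples — but is
generic for any 2 × (case, control) design.

It is aimed at computational biologists who have per-cytosine
methylation counts (e.g. Bismark-style cytosine reports), a gene
annotation (GFF3/BED), and either an expression count matrix or an
externally computed differential-expression table, and who want
reproducible consensus DMRs and methylation × expression cross-tables.

## Method in brief

Per cytosine with methylated count $k$ and coverage $n$, within each
pair:

* frequency $f = k/n$, with a 95% binomial likelihood-ratio (Wilks)
  confidence interval $\{p : 2[\ell(\hat f) - \ell(p)] \le \chi^2_1(0.95)\}$;
* transform $v = \ln\frac{1+f}{1-f}$, with
  $\mathrm{SD}(v)$ = (transformed CI length)/6;
* two-observation least squares $Y = b_0 + b_1 \cdot \mathrm{group}$
  (group coded $-1$ control, $+1$ case), so
  $b_1 = (v_\mathrm{case} - v_\mathrm{ctrl})/2$,
  $\mathrm{SD}(b_1) = \tfrac12\sqrt{\mathrm{SD}_\mathrm{ctrl}^2 + \mathrm{SD}_\mathrm{case}^2}$,
  and the site score $z = b_1/\mathrm{SD}(b_1)$ ($z>0$:
  hyper-methylated in the case group).

Flagged sites ($|z| \ge z_{1-\alpha/2}$) are merged into regions by
gap-bounded runs (defaults: gap ≤ 500 bp, ≥ 3 sites, Stouffer region
score $\sum z_i/\sqrt n$). A region is a **consensus** DMR only when
both pairs call the same direction on an overlapping interval. Consensus
regions are assigned to promoter windows (TSS ± 1000 bp, strand-aware)
and gene bodies; genes whose bodies carry both directions are "mixed"
and excluded from the unique-signal association. Expression classes use
the strict thresholds p < 0.005 with fold change > 1.5 (up) or < 0.6
(down), on a built-in stand-in test or an imported DE table. The final
report crosses the methylation categories with the up/down sets.

See `docs/methods.md` for assumptions, the calibration properties of
the SD = CI/6 rule, and everything the synthetic generator does and
does not emulate.

## Worked example

Simulate a synthetic world (four count tracks, annotation, expression
matrix, with planted truth) and run the pipeline end to end:

```
dmrlink simulate --seed 1 --outdir sim/
dmrlink run-all --config pipeline.yaml --outdir out/
```

where `pipeline.yaml` points at the simulated files:

```yaml
pileups:
  ctrl_male:   sim/ctrl_male.cytosine.tsv
  as_male:     sim/as_male.cytosine.tsv
  ctrl_female: sim/ctrl_female.cytosine.tsv
  as_female:   sim/as_female.cytosine.tsv
annotation: sim/genes.gff3
counts: sim/expression_counts.tsv
```

The same run through the library:

```python
from dmrlink import SimConfig, PipelineConfig, simulate, write_all, run

paths = write_all(simulate(SimConfig(seed=1)), "sim")
result = run(PipelineConfig(
    pileups={k: str(paths[k]) for k in
             ("ctrl_male", "as_male", "ctrl_female", "as_female")},
    annotation=str(paths["gff3"]),
    counts=str(paths["counts"]),
    outdir="out",
))
print(result["report"].counts)
print(result["report"].identities)
```

which prints (seed 1, package defaults — 50 planted DM elements,
mostly hypo-methylated, on a 2 × 2 Mb genome with 200 genes):

```
{'promoter_hyper': 12, 'promoter_hypo': 46, 'body_unique_hyper': 15,
 'body_unique_hypo': 46, 'body_mixed': 1, 'up': 21, 'down': 11}
{'total_dm': 119, 'n_hypo': 92, 'hypo_share_pct': 77, 'n_de': 32,
 'up_share_pct': 66}
```

Reading this: 114 consensus DMRs were called from ~79k covered sites;
46 distinct consensus regions overlap promoter windows in the hypo
direction and 12 in the hyper direction (region units), 46 genes carry
a uniquely hypo-methylated body and 15 a uniquely hyper-methylated one
(gene units), 1 gene is mixed and excluded. Of the four-category total
(119), 77% is hypo-methylated — the planted hypo-dominant world — and
21 of 32 DE genes (66%) are up-regulated. `out/` also contains the
per-site contrast TSV, per-pair and consensus BEDs, the per-gene status
table, the DE table, per-intersection gene lists and a run manifest
(parameters + input checksums); identical inputs and config reproduce
all outputs byte-for-byte.

## Acceptance script

`scripts/acceptance.py` regenerates the synthetic dataset at the given
seed, runs every pipeline stage from scratch, prints the report summary
to stderr, and writes its JSON result to `--out`:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
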