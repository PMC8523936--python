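# hicomp

Comparative Hi-C analysis of a replicated two-group design, built around
the questions raised by late fetal muscle development in pig: how do
A/B chromatin compartments, TADs, pairwise contacts and telomere
clustering differ between 90 and 110 days of gestation?

The package implements the full downstream analysis — from binned
contact matrices to tested biological conclusions — together with a
seeded synthetic-data generator that plants every structure the
analysis is meant to recover, so the whole pipeline is verifiable
end-to-end on ground truth.

## What it computes

Given HiC-Pro-style contact matrices for 2 groups × 3 replicates
(`d90`, `d110`), TAD call sets, a gene-expression table and 3D-FISH
signal coordinates:

* **Matrix layer** — ICE balancing per chromosome, map merging by
  group, the maximal-resolution rule (a bin size is claimable when ≥80%
  of bins cumulate ≥1,000 interactions), and the stratum-adjusted
  correlation coefficient (SCC) as a replicability index.
* **Compartments** — A/B calling per chromosome as the leading
  eigenvector of the observed/expected Pearson correlation matrix, sign
  oriented by gene density; segment counting with NA bridging; a
  Poisson GLM `log y ~ α·c + β_group` testing compartment
  fragmentation between groups; consistent switches (`AAA→BBB`); a
  segment-shuffling permutation test of cross-sample label consistency;
  gene density / expression contrasts between A and B (Wilcoxon).
* **TADs** — reciprocal-overlap identity (`≥90%` of both intervals),
  stable and group-specific TAD sets, and the boundary Interaction
  Score: IS = proportion of contacts crossing a boundary among all
  contacts within ±500 kb, cyclic-loess normalized across samples, with
  ΔIS = mean(d110) − mean(d90) contrasted between the two
  group-specific boundary classes.
* **Differential interactions** — union count table at 500 kb, ≥30
  reads/6 samples filter, cyclic-loess offsets, a negative-binomial GLM
  (log link, group fixed effect, Cox–Reid-adjusted dispersion) with
  likelihood-ratio tests and genome-wide Benjamini–Hochberg FDR.
* **BODIs** — bins classified positive/negative when their significant
  cis DIs are ≥10:1 of one logFC sign, merged into Blocks Of
  Differential Interactions; block-size enrichment against a
  genome-wide logFC-shuffling permutation null; A/B composition with a
  Fisher exact test; expression logFC contrast between block signs.
* **Telomeres** — binomial enrichment of trans DIs touching the
  terminal 2 Mb of chromosome arms, and the 3D-FISH association test:
  nuclei with 4 signals are *associated* when any heterologous probe
  pair lies ≤1 µm apart, and conditions are compared by a grouped
  binomial GLM χ² (likelihood-ratio) with the telomeric pair as a fixed
  covariate.

## Worked example

The bundled generator simulates the default toy study — 3 chromosomes
× 30 Mb, 2 groups × 3 replicates, ~2 M cis contacts per replicate —
with planted compartments (fragmented and 3% switched in d110), TADs
(10 group-specific per chromosome and group), one positive and one
negative 3 Mb differential block per chromosome, and a 4-fold d90 boost
on subtelomeric trans pairs:

```python
from hicomp import pipeline, simulate

config = pipeline.RunConfig(outdir="run")
config.sim = simulate.SimConfig(seed=1)
results = pipeline.run_pipeline(config)        # ~10 s
metrics = pipeline.validate_recovery(results)
```

At seed 1 the run reports (from `run/report.json` and `metrics`):

| quantity | value | meaning |
|---|---|---|
| compartment label agreement | 1.00 | per-replicate A/B calls vs planted labels |
| switch precision / recall | 1.00 / 1.00 | consistent `AAA→BBB` bins vs truth |
| consistency fraction | 96.2% (p = 0.001) | bins labelled identically 6/6, segment-shuffle null |
| group-specific TAD precision | 1.00 / 1.00 | d90- and d110-specific calls vs truth |
| mean ΔIS (d90- / d110-specific) | +0.036 / −0.039 | boundary insulation gained vs lost (Wilcoxon p = 2×10⁻¹⁹) |
| significant DIs | 1,880 of 16,290 (87.0% cis) | NB GLM, q ≤ 0.05 |
| planted block-pair recall | 0.79 | in-block pairs recovered among significant DIs |
| BODI block p-values | 0.0099 / 0.0099 | ≥6-bin positive/negative blocks, 100 permutations |
| subtelomeric negative-trans p | 7×10⁻⁹⁴ | binomial enrichment at chromosome ends |
| SCC within / between groups | 0.89 / 0.40 | replicability index |

ΔIS separates the two boundary classes in the planted directions:
boundaries of d90-specific TADs *gain* contacts (positive ΔIS, the
domain dissolves by d110) while d110-specific boundaries *lose* them.
Applying the FISH condition test to the published association counts of
the three probed telomere combinations (24/100 vs 15/100, 19/99 vs
15/100, 28/100 vs 20/97) gives χ² = 4.38, p = 0.036 with higher
association at 90 days.

The same stages are exposed on the command line:

```bash
hicomp run --seed 1 --out run          # full pipeline + report.json
hicomp simulate --seed 1 --out data    # just the synthetic dataset
hicomp diffint data/d90_rep*.matrix data/d110_rep*.matrix data/bins.bed \
    --fdr 0.05 --out di.tsv
hicomp validate --seed 1 --out run     # recovery metrics vs ground truth
```

## Layout

```
src/hicomp/
  genome_io.py     bin tables, sparse contact maps, HiC-Pro/BED/TSV I/O
  normalize.py     ICE, cyclic loess, SCC replicability
  simulate.py      seeded generator with planted ground truth
  compartments.py  A/B calling, fragmentation, switches, expression
  tads.py          identity matching, stable/specific sets, IS and ΔIS
  diffint.py       NB GLM differential interactions, BH FDR
  bodi.py          block discovery, permutation null, composition
  telomere.py      subtelomeric enrichment, FISH association statistics
  pipeline.py      orchestration, manifest, recovery validation
  cli.py           click command line (`hicomp ...`)
docs/methods.md    model assumptions, parameter choices, limitations
```
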