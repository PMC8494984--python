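# triopattern

Parent–hybrid trio expression-pattern analysis for diallel crosses.

In hybrid-breeding transcriptomics, a central question is how a hybrid's
gene expression relates to that of its two inbred parents: which genes are
switched on or off relative to the parents, and, for co-expressed genes,
where the hybrid sits between (or beyond) the parental levels. This
package implements that analysis for an incomplete (NCII) diallel — a set
of inbred lines crossed pairwise into hybrids, each measured by RNA-seq
(gene-level FPKM) across tissues with replicates. Its intended users are
researchers studying heterosis who want the trio pattern classification
and its diallel-wide summaries as tested, scriptable building blocks.

## The model

For each gene in a (parent1, parent2, F1) trio, replicate-mean FPKM ≥ 1
defines the expressed state of each member, and the three on/off flags
give one of five qualitative models: **PCE** (parents only), **PSE** (one
parent only), **HSE** (hybrid only), **SPE** (hybrid + one parent) — the
presence–absence (PAV) patterns — and **PHCE** (all three expressed).
PHCE genes are scored by the dominance statistic

    A = (Pmax − F1) / (Pmax − Pmin)

(Pmax, Pmin: the higher-/lower-expressing parent). Seven half-open
intervals of A define **PSD** (A < 0), **PD** [0, 0.2), **PPD** [0.2, 0.4),
**MP** [0.4, 0.6), **PND** [0.6, 0.8), **ND** [0.8, 1.0) and **NSD**
(A ≥ 1) — from expression above the high parent, through midparent
(additive) behaviour, to below the low parent.

On top of the classifier the package provides parental-abundance
asymmetry counts, per-hybrid pattern-proportion tables, focal-hybrid
contrasts against the mean of the other hybrids, Venn-exclusive
hybrid-specific gene sets, and hypergeometric gene-set enrichment with
Benjamini–Hochberg FDR. A synthetic-data generator plants all eleven
pattern classes at known proportions with controllable replicate noise,
so every stage is testable against ground truth.

## Worked example

```python
import pandas as pd
from triopattern import (SimulationConfig, simulate, build_trios,
                         classify_trios, recovery_report, summarize_patterns,
                         hypergeom_test)
from triopattern.summary import format_percent

cfg = SimulationConfig(n_genes=2000, noise_cv=0.1, seed=42)
ds, truth = simulate(cfg)                       # 4 parents x 6 hybrids x 3 tissues
calls = pd.concat([classify_trios(build_trios(ds, t)) for t in ds.tissues],
                  ignore_index=True)
print("trios classified:", len(calls))
print("recovery accuracy:", round(recovery_report(calls, truth).accuracy, 4))

s = summarize_patterns(calls, "ZC", "S")        # hybrid ZC, seed tissue
print("ZC seed: PAV share", format_percent(s.pav_proportion), "%")
print("ZC seed: SPE share of PAVs", format_percent(s.pav_shares["SPE"]), "%")
print("ZC seed: NSD share of PHCE", format_percent(s.phce_shares["NSD"]), "%")
print("hypergeom P[X>=4] =", hypergeom_test(4, 4, 5, 10))
```

prints

```
trios classified: 36000
recovery accuracy: 0.9321
ZC seed: PAV share 20.35 %
ZC seed: SPE share of PAVs 45.45 %
ZC seed: NSD share of PHCE 31.01 %
hypergeom P[X>=4] = 0.023809523809523787
```

36,000 trios are 2,000 genes × 6 crosses × 3 tissues. With 10% replicate
noise, 93.2% of planted pattern classes are recovered exactly (errors
concentrate in the narrow middle dominance categories); with
`noise_cv=0` the accuracy is exactly 1.0. The ZC seed summary shows
roughly one call in five is a presence–absence difference, SPE is the
largest PAV class, and NSD the largest dominance category — the planted
mix. The last line is the upper-tail hypergeometric probability of
drawing 4 annotated genes in a query of 4 from a 10-gene universe with 5
annotated: C(5,4)/C(10,4) = 5/210.

The same pipeline runs from the shell:

```
triopattern run-all --n-genes 2000 --seed 42 --out results/demo
triopattern simulate --shared-parents --n-genes 2000 --seed 1 --out data/   # 10-genotype, 90-sample layout
triopattern classify --matrix data/matrix.tsv --samples data/samples.tsv \
    --design data/design.tsv --out results/calls
```

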