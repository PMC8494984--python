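# Methods

## The trio classification model

The unit of analysis is a *trio*: two inbred parents and their F1 hybrid,
measured as gene-level FPKM in the same tissue. For each gene, replicate
FPKM values are averaged per genotype × tissue (arithmetic mean by default,
median optionally) and a genotype is called *expressing* the gene when the
aggregated value is ≥ 1 FPKM. The threshold is applied to the aggregated
value rather than per replicate; both conventions are defensible and the
stage at which the cut is applied is configurable through
`aggregate_replicates`/`build_trios` arguments. Genes non-expressed in all
three trio members carry no pattern information and are excluded before
classification.

The three on/off flags then determine one of five qualitative models:

| p1 | p2 | F1 | model |
|----|----|----|-------|
| on | on | on | PHCE (parental–hybrid co-expression) |
| on | on | off | PCE (parental co-silence) |
| one on | — | off | PSE (parent-specific expression) |
| off | off | on | HSE (hybrid-specific expression) |
| one on | — | on | SPE (single-parent expression) |

PCE, PSE, HSE and SPE are presence–absence (PAV) patterns. For the
one-parent models the identity of the expressing parent is recorded, which
supports high-/low-parent bias analyses downstream.

PHCE genes are placed on a quantitative dominance scale via

    A = (Pmax − F1) / (Pmax − Pmin)

with Pmax/Pmin the higher-/lower-expressing parental mean. A is 0 at the
high parent, 0.5 at the midparent, 1 at the low parent; values outside
[0, 1] are transgressive. Seven half-open intervals define the categories
PSD (A < 0), PD [0, 0.2), PPD [0.2, 0.4), MP [0.4, 0.6), PND [0.6, 0.8),
ND [0.8, 1.0) and NSD (A ≥ 1). Interval bounds are lower-inclusive and
compared directly in floating point — no epsilon is added, so a gene with
A exactly 0.2 is PPD by construction.

**Degenerate parents.** When the two parental means are exactly equal the
ratio is undefined. Rather than fabricating a value, the call is made by
sign: F1 above the common parental value → PSD, below → NSD, equal → MP,
and `a_value` is recorded as undefined. With continuous data exact ties
essentially only arise from duplicated input rows, but the rule keeps the
classifier total.

Two code paths produce identical output: a scalar truth-table walk
(`classify_trio`), which doubles as the naive reference, and a vectorized
numpy path (`classify_trios`) used by the pipeline. Their exact agreement
on random trios is asserted in the test suite.

## Diallel summaries

*Parental asymmetry* counts, for a pair of inbreds, the genes more
abundant in one parent than the other. The source study reports such
counts (and flags ≈3:1 ratios); its differential criterion is unstated, so
the package uses a documented reconstruction: |log2((a+1)/(b+1))| ≥ 1 on
replicate-mean FPKM, optionally tightened by a Welch t test on
log2(FPKM+1) replicates with BH FDR ≤ 0.05 (`DegRule`). Genes failing the
rule count as equal and are reported explicitly as `n_eq`.

*Pattern summaries* report, per hybrid × tissue, the PAV share of all
calls, each PAV model's share within PAVs, and each dominance category's
share within PHCE. Percentages are formatted to two decimals with half-up
rounding. *Focal contrasts* compare one class proportion in a focal hybrid
against the unweighted arithmetic mean of the same proportion over the
other hybrids (hybrids averaged as units, not pooled by gene counts), with
`relative_excess = focal/rest_mean − 1`. *Hybrid-specific genes* are the
Venn-exclusive region of each hybrid's qualifying set within a tissue; the
default qualifying set is the hybrid's differential set (PAV calls plus
PHCE genes changed ≥ 2-fold against either parent), with the
expressed-gene set as the configurable alternative.

## Enrichment

Over-representation of a query list against annotated gene sets uses the
upper-tail hypergeometric probability P[X ≥ k], summed in log space from
log-gamma binomial terms so small p values keep full relative precision
(verified to 1e−12 relative error against exact integer arithmetic). All
sets hit by the query form one BH family; q ≤ 0.05 flags significance.
Only over-representation is tested, the universe is an explicit input, and
annotation files (GMT or long TSV) are taken at face value — no ontology
graph propagation.

## The synthetic-data generator

The generator emulates the target study structure: 4 inbreds (Z, C, M, Q),
their 6 NCII hybrids, 3 tissues (L, E, S), 3 replicates. Per gene × cross ×
tissue it draws a terminal class from an 11-class mix whose default echoes
the reported diallel-wide proportions (PAV 19.18% of calls; SPE/PSE
43.73/41.07% of PAVs; NSD/PSD 31.06/24.30% of PHCE; the PCE:HSE split
within the PAV remainder, 0.10:0.052, is the generator's own choice). The
mix can be overridden per hybrid × tissue, e.g. to plant an elevated SPE
share in one hybrid's seed.

Noise-free means realize each class exactly:

- "On" levels are log-normal (ln-mean 3.0 ≈ 20 FPKM, ln-sd 0.8), floored
  at 2 FPKM so aggregation noise cannot silence them at realistic CVs;
  "off" levels are 0 by default (configurable to a sub-threshold positive
  value to exercise the FPKM < 1 rule).
- PHCE genes get Pmin floored at 2.5 FPKM and a parental fold gap drawn
  log-uniformly from [2, 6]. For NSD the gap is capped at [2, 2.2] because
  the planted F1 = Pmin − 0.3·(Pmax − Pmin) would otherwise fall below the
  expression threshold (or zero).
- The F1 mean is placed so the exact A value sits at the target category's
  interval midpoint (PD 0.1, PPD 0.3, MP 0.5, PND 0.7, ND 0.9), with the
  open-ended categories 0.3 beyond their boundary (PSD −0.3, NSD 1.3).
  Every planted gene is thus ≥ 0.1 in A-distance from the nearest
  boundary, so noise-free recovery is exact and noisy recovery degrades
  smoothly with CV.

Replicate noise is a multiplicative log-normal factor with unit mean and
chosen coefficient of variation — chosen over negative-binomial counts
because the pipeline consumes FPKM, not counts, and no dispersion
information is available for the target data. All randomness flows from
one `numpy` Generator seeded by the config, so identical configs produce
byte-identical output files.

**Layouts.** Because crosses share parents, exact per-cross pattern
control is impossible with only 10 genotypes: a gene cannot be "expressed
in Z" for cross ZC and "silent in Z" for cross ZM. The default
*independent-parents* layout therefore writes parental values into
cross-specific pseudo-genotypes (`ZC_Z`, `ZC_C`, …; 18 genotypes, 162
samples), giving exact control of every planted class. The
*shared-parents* layout reproduces the real 10-genotype × 90-sample
design: parental on/off states and levels are drawn once per parent (off
probability 0.15), hybrid states emerge per cross, and the ground truth is
recorded post hoc by classifying the noise-free means.

**What passing tests show.** The generator plants patterns at safe
distances from every decision boundary and draws replicates independently.
Real FPKM data has correlated replicates, genes near the 1-FPKM threshold,
length/library-size artifacts, and A values arbitrarily close to interval
boundaries, so recovery accuracy on synthetic data is an upper bound on —
not an estimate of — accuracy on real data. What the tests do establish is
that the classifier itself is exact (any miscall at cv = 0 would be a
code defect) and that its noise sensitivity is concentrated in the narrow
middle categories (PD/PPD/MP/PND), as error propagation of the A ratio
predicts.

## Problem sizes and numerical choices

The default simulation sizes used in the tests and the acceptance script
(1,000–5,000 genes; the full 18-combination diallel or a single tissue for
noise sweeps; 10,000 random trios for classifier cross-checks; exhaustive
hypergeometric verification for universes up to N = 30 plus dense random
sampling to N = 200) were chosen to give stable Monte-Carlo estimates —
binomial standard errors below half a percentage point on the headline
accuracies — while keeping a full run in seconds.

Other numerical choices: interval comparisons are direct (`<`, `>=`) with
no tolerance; replicate means use pandas' pairwise summation; percentages
are formatted via `Decimal` half-up from the shortest float repr;
output TSVs are written with fixed float formats so reruns are
byte-identical; BH adjustment delegates to statsmodels, Welch tests to
scipy.

## Known limitations

- The A statistic uses aggregated means only; replicate variance does not
  feed the classification, so no per-gene confidence accompanies a call.
- The differential-expression rule is a reconstruction, not the source
  study's (unstated) criterion; asymmetry counts and qualifying sets
  depend on it.
- Equal-parental-mean trios use the sign rule described above, which is a
  package convention, with occurrences counted rather than hidden.
- The generator does not model tissue correlation, gene length, library
  size, or count-level dispersion.
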