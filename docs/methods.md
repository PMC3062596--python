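# Methods

## Scope and data model

The pipeline consumes four plain-text inputs — FASTA sequences, a
per-residue disorder annotation table (scores in [0, 1] and/or binary
labels), a protein→COG assignment table, and an organism metadata table —
plus a protein→organism mapping, and joins them into an in-memory dataset.
The disorder predictor itself is out of scope: annotations are inputs, in
the one-row-per-residue layout that per-residue predictors such as VSL2B
emit. Binarization uses `score >= threshold` (default 0.5, configurable);
a residue exactly at the threshold is called disordered. Coordinates are
0-based half-open in memory and 1-based inclusive in every file.

Non-standard residue letters (X, B, Z, U, …) occupy positions during region
segmentation — they carry a disorder label like any residue — but are
excluded from the 20-residue composition vectors, whose formulas are defined
over the standard alphabet only.

A protein assigned to several COGs is stored once; every collection-level
aggregate (per COG, per functional group, per organism, per superkingdom)
counts each distinct protein once per collection, so group totals need not
equal the sum of member-COG totals.

## Region statistics

Regions are maximal runs of constant disorder state; the regions of a
protein tile it exactly (contiguous, alternating kinds). Length classes
*L* ≥ 1, 11, 21, 31, 41 AA are inclusive thresholds throughout, which makes
every count and percentage non-increasing in *L* — a property the test
suite asserts.

Per-100-AA and percent statistics are **pooled** by default: sum of
qualifying-region counts (or residues) over sum of protein lengths in the
collection. Pooling is the only convention under which the "all proteins"
and "proteins containing regions" variants of the same statistic are
commensurable; a per-protein-mean variant is exposed as an option for
sensitivity checks. Ratios with a zero denominator (e.g., region-basis
density when no region qualifies) are reported as missing (NaN), never 0.
The "more than 90% disordered" purity flag uses the strict inequality.

## Composition

Mole fractions are length-weighted means of per-sequence frequencies, which
equal pooled counts over total residues; the implementation counts pooled
and the test oracle recomputes fractions independently per sequence.
Fractional differences with a zero reference fraction are undefined (NaN)
rather than ±∞, so rankings remain total: ascending order with NaN last,
ties broken alphabetically for determinism. The algebraic identity
fd(b,a) = −d/(1+d) for d = fd(a,b) is used as a self-check.

The reporting layer emits both candidate normalizations of the
"% in proteins containing disordered regions" composition column —
relative to all residues and relative to that protein subset's residues —
explicitly labelled, since either convention is defensible.

## Discretization and cross-tables

GC content: low/medium/high with borders at the collection mean ± 1 sample
SD (ddof = 1); borders are inclusive to medium, and a constant collection is
all-medium. The borders are computed over exactly the organism set being
analysed; the full pipeline stratifies by superkingdom by default (tables
are reported per superkingdom), with a joint mode available. Genome size:
short iff < 4 Mb for bacteria, < 2.5 Mb for archaea — a genome exactly at
the cut is long because "short" is defined by the strict inequality.
Organism disorder level (percent of residues in disordered regions ≥ 41 AA,
pooled over the proteome) is discretized with the same mean ± 1 SD scheme by
default, for symmetry with GC; a tertile mode (ties broken by organism id)
exists because no canonical cutpoints are established for this attribute.
"Psychrophile" is normalized to "cryophile".

Cross-tables report, for each pair of characteristic modalities and each
functional group, the pooled percent of residues inside disordered and
inside ordered regions of the focus length class over all proteins of the
cell's organisms; the remainder to 100% is residues in sub-threshold
regions. Empty cells are missing, not zero.

## Statistical testing

Between-category comparisons use Welch's unequal-variance two-sided t-test
(group sizes and variances are routinely unequal here), after reducing each
category to its ⌈0.25·n⌉ most disordered proteins — long-length-class
disorder is heavily zero-inflated, so full-distribution comparisons mostly
compare the zero mass. Ties at the cut are included deterministically by
original index. Two constant equal samples give p = 1 by convention.

The one-sample Kolmogorov–Smirnov normality check runs against a normal
with the sample's own mean and SD; with estimated parameters the p-value is
approximate (anti-conservative), and it is used as a screen, not an
endpoint. No multiple-testing correction is applied by default;
Benjamini–Hochberg is available.

A calibration caveat the test suite documents: the top-25% reduction makes
the t-test anti-conservative under the null (the reduced samples are means
of correlated upper order statistics, not iid draws). Without the
reduction the empirical type-I error is nominal (0.05 ± 0.02 over 1,000
simulated replicates); with it, inflation up to roughly 3× nominal is
observed in small samples. Conclusions drawn from the reduced comparison
should therefore rest on very small p-values, which is how the pipeline's
recovery checks use it (p < 0.01 under a planted effect).

## Rule mining

Frequent itemsets come from a level-wise apriori with join and
subset-pruning steps; rules are every body/head bipartition of a frequent
itemset meeting the confidence floor (head size 1 by default, as in
standard mined-rule reports; all bipartitions available). Support is
counted over organisms — one transaction each; empty-attribute values are
simply absent from the transaction. The filter applies, in order:
dominant-item exclusion (data-driven configuration, not hard-coded taxa),
body-size bound (≤ 2), required disorder attribute, minimal-body
enforcement (a rule is dropped when a strictly smaller body with the same
head is at least as reliable — a strictly more reliable superset-body rule
survives), and one-rule-per-(head, body-attribute-set) deduplication.
"Most reliable" is lexicographic on (confidence, support, lift); confidence
is listed first because it is the primary quality measure, then support,
then lift. Default mining thresholds are support ≥ 0.13 / confidence
≥ 0.66 for bacteria and ≥ 0.16 / ≥ 0.90 for archaea.

## Synthetic generator

The generator emulates the joint structure the analysis exploits, with all
randomness from one seeded `numpy.random.Generator` (identical seed+config
⇒ byte-identical outputs):

* **Organisms.** GC is drawn from a three-component normal mixture
  (defaults 34 ± 3, 49 ± 5, 70 ± 3 with weights 0.15/0.60/0.25), spanning
  the ~25–75% range of real prokaryotic genomes and making the high-GC
  modality a populated cluster rather than a Gaussian tail. Genome size is
  lognormal (median ≈ 3.2 Mb); phylum, habitat, oxygen and temperature are
  categorical with realistic skews (e.g., 70% mesophiles).
* **Disorder.** Protein labels are alternating geometric runs. The
  disordered-run mean is 18 AA, so run-length frequencies decay
  monotonically and every length class up to ≥ 41 AA is populated at the
  defaults. Each group's stationary disordered fraction (Isp 0.30, Cp 0.33,
  Me 0.13, Pc 0.17, NC 0.15 — an Isp/Me ratio ≥ 2) is shifted per organism
  on the logit scale by `gc_coupling · z(GC) + ε`, ε ~ N(0, 0.25²), with
  `gc_coupling = 1.2`; z uses the mixture's analytic moments so generation
  never depends on the sampled cohort. Because the logistic link saturates,
  configured group ratios are exact conditional on zero shift and
  compressed marginally — the recovery tests check ordering, not the raw
  ratio.
* **Composition.** Background residue frequencies are Swiss-Prot-like;
  inside disordered runs the disorder-promoter mass (A, E, K, P, Q, R, S)
  is multiplied by 1.5 and renormalized, which simultaneously depletes the
  remaining residues; Gly/Ala/Arg/Pro are mildly up-weighted with GC to
  mimic GC-driven composition drift. Protein lengths are lognormal with
  mean ≈ 290 AA (floored at 60), matching typical prokaryotic averages.
* **Scores.** When requested, disordered residues get
  `thr + (1−thr)·Beta(2,2)` and ordered residues slightly less than
  `thr·Beta(2,2)`, so thresholding at `thr` reproduces the labels exactly
  and both input paths (scores, labels) are exercised.

What the generator does **not** emulate: sequence homology and gene
families, phylum-specific composition beyond the configured couplings,
operon/length correlations, annotation noise, and real predictor error
structure. Passing recovery tests therefore show that the pipeline's
machinery is correct and sensitive at realistic effect sizes — not that any
particular biological conclusion transfers to real proteomes.

## Problem sizes and defaults

Default study conditions are 60 organisms (40 bacteria, 20 archaea) × 200
proteins. The end-to-end recovery check runs 20 seeded replicates of
generation plus analysis (≈ 1.5 s each); oracle checks use 1,000 random
label vectors (lengths up to 5,000), 500 random sequence sets, and 200
random mining instances with ≤ 12 items cross-checked against exhaustive
enumeration; null calibrations use 1,000 t-test replicates and 2,000
transactions. `scripts/acceptance.py` reports recovery rates over 10
replicates seeded from `--seed`.

## Known limitations

* The per-100-AA pooled-vs-averaged ambiguity is resolved by convention
  (pooled); results under the other convention can differ for collections
  with wide length variation.
* The mean ± 1 SD disorder discretization is sensitive to the organism set;
  with few organisms the "low"/"high" classes can be empty, and rule mining
  then yields no disorder rules (an empty, well-formed output — not an
  error).
* KS p-values with estimated parameters are approximate; use a dedicated
  Lilliefors table if the normality screen itself is of interest.
* The apriori implementation targets organism-scale transaction sets
  (hundreds of transactions, tens of items); it is exact but not tuned for
  market-basket scale.
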