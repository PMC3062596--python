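# disprok

Proteome-wide statistics of **intrinsically disordered protein regions** in
prokaryotes: from per-residue disorder annotations (e.g., VSL2B-style
predictor output), COG functional assignments and genome metadata, the
package computes disordered-region statistics by length class, amino-acid
composition contrasts between disordered and ordered regions, organism-
characteristic cross-tables, and association rules linking genomic and
ecological traits (GC content, genome size, habitat, oxygen requirement,
growth temperature) to proteome disorder level.

It is aimed at structural bioinformaticians studying how disorder content
varies across functional categories (COGs and their groups Isp, Cp, Me, Pc)
and across organism characteristics, and at anyone needing a tested,
reproducible reimplementation of this analysis style. A synthetic-proteome
generator with planted effects makes every stage verifiable offline, without
genome downloads or running a disorder predictor.

## The statistics at the core

* A **disordered region** is a maximal run of consecutive residues labelled
  disordered (label 1, or score ≥ threshold, default 0.5). Regions are
  reported for length classes *L* ≥ 1, 11, 21, 31, 41 AA (inclusive).
* The **mole fraction** of amino acid *j* over a sequence set is the
  length-weighted mean of per-sequence frequencies,
  *P<sub>j</sub>* = Σ<sub>i</sub> *n<sub>i</sub> P<sub>ji</sub>* / Σ<sub>i</sub> *n<sub>i</sub>*,
  identical to pooled counting. The **fractional difference** between the
  disordered set *a* and ordered set *b* is
  (*P<sub>j</sub>(a)* − *P<sub>j</sub>(b)*) / *P<sub>j</sub>(b)*; it is
  positive for disorder-promoting residues (A, E, K, P, Q, R, S) and
  negative for order-promoting ones (C, F, H, I, L, V, W, Y).
* Organism characteristics are discretized into **modalities**: GC content
  low/medium/high at mean ± 1 SD, genome size short/long at 4 Mb (bacteria)
  or 2.5 Mb (archaea), plus categorical habitat/oxygen/temperature.
* Between-category comparisons reduce each category to its **25% most
  disordered proteins** and apply Welch's t-test, with a Kolmogorov–Smirnov
  normality screen.
* **Association rules** A ⇒ B over one-transaction-per-organism item sets
  are mined with an in-repo apriori and scored by support
  s = σ(A∪B)/N, confidence c = σ(A∪B)/σ(A) and lift = c/s(B) (lift = 1
  under independence), then filtered: ≤ 2 body items, a disorder item
  somewhere in the rule, minimal bodies, configurable exclusion of dominant
  items, and one rule per (head, body-attribute) pattern ranked by
  (confidence, support, lift).

## Worked example

```python
from disprok import GeneratorConfig, generate, analyze, RunConfig
from disprok.regions import pct_proteins_with_region, pct_disordered_aa
from disprok.grouping import proteins_in_group

cfg = GeneratorConfig(seed=7, n_bacteria=10, n_archaea=5, proteins_per_organism=60)
dataset, truth = generate(cfg)
for g in ("Isp", "Cp", "Me", "Pc", "NC"):
    members = proteins_in_group(dataset.proteins, g)
    print(g, len(members),
          round(pct_proteins_with_region(members, 41), 1),
          round(pct_disordered_aa(members, 41), 2))
result = analyze(dataset, RunConfig())
print(result.rules["Bacteria"][1])
```

prints

```
Isp 198 40.4 10.93
Cp  197 40.1 11.89
Me  283 20.8  4.99
Pc  150 26.0  6.57
NC  122 24.6  5.80
{gc=medium} => {disorder=medium} (s=0.500, c=1.000, lift=1.667)
```

The generator planted more and longer disordered runs in the
information-storage (Isp) and cellular-process (Cp) groups than in
metabolism (Me): the percentage of proteins containing a disordered region
of ≥ 41 AA (third column) and the percent of residues inside such regions
(fourth column) recover that ordering, and rule mining over the 15
organisms links GC modality to disorder modality.

The same pipeline runs from files via the CLI:

```sh
disprok simulate --seed 7 --out data/
disprok analyze --data data/ --out report/
```

`report/` then holds region statistics, purity, composition and
fractional-difference tables, cross-tables for every characteristic pair,
t-test results, COG orderings and filtered rules (TSV + DOT), all stamped
with a config hash.

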