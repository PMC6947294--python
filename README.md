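# phylostress

Phylostratigraphic age, Ka/Ks divergence and network-evolution statistics
for stress-associated gene sets.

## The problem

Plants meet heat, cold, drought, salt, osmotic, light and oxidative stress
with gene networks that themselves evolve. Two per-gene indices summarise
that history:

* **PAI** (phylostratigraphic age index): the rank of the most basal
  internode of the focal species' lineage shared with any species carrying
  a detectable ortholog (sequence identity ≥ a threshold, 0.5 by default).
  Lower PAI = older gene; genes with no ortholog outside the focal species
  sit in the terminal, species-specific phylostratum.
* **DI** (divergence index): Ka/Ks between the focal gene and its closest
  ortholog in a sister species, estimated with the Nei–Gojobori (1986)
  method and Jukes–Cantor correction. DI < 1 indicates purifying
  selection, ≈ 1 neutral evolution, > 1 positive selection; genes with
  Ks = 0 are excluded as uninformative.

Whether a stress gene set is older or more conserved than the genome is
decided by a **shuffling test**: draw N<sub>perm</sub> random same-size sets
from the background without replacement and count, for each statistic
(mean, chi-square against the background distribution, per-bin frequency
difference df<sub>i</sub> = f<sub>i,stress</sub> − f<sub>i,background</sub>),
the replicates n<sub>rand</sub> exceeding the observed value; the empirical
p-value is exactly n<sub>rand</sub>/N<sub>perm</sub>, flagged on both
tails (p < α and p > 1 − α).

At the network level the package computes the degree–age Pearson
correlation r(k, PAI), the scalar age assortativity r<sub>a</sub> (Pearson
correlation of PAI over the 2|E| directed edge ends) with its jack-knife
standard deviation, the |dPAI| distribution at shortest-path distances
1 / 2 / ≥3, per-cluster internal/external degrees, hypergeometric term
enrichment with Benjamini–Hochberg correction, and GO-term × age profiles
normalised to 100%.

A first-class synthetic-data module generates every input — lineage,
ortholog hits with detection noise, codon pairs evolved under known dN/dS,
networks with planted age assortativity, stress sets with exact planted
overlaps — together with its truth tables, so every estimator ships with a
recovery test and the whole pipeline runs with no database access.

## Worked example

`python examples/04_network_statistics.py` plants positive age
assortativity (edge weight ∝ exp(−β·|dPAI|), β = 0.8) in a 120-gene
network and recovers it:

```
network: 114 nodes, 200 edges (mean degree 3.51)
age assortativity r_a = 0.906 +/- 0.017 (Np = 200 interacting pairs)
degree-age Pearson r = 0.165 (p = 0.079)

|dPAI| by shortest-path distance (fractions):
  distance 1:   200 pairs, 38.5% with identical age
  distance 2:   599 pairs, 20.9% with identical age
  distance >=3:  5418 pairs, 3.9% with identical age
```

r<sub>a</sub> ≫ σ(r<sub>a</sub>) confirms the planted signal: directly
interacting genes share their age far more often than distant pairs. The
other scripts in `examples/` walk through PAI assignment
(`01_gene_ages.py`), the DI census and selection classes
(`02_divergence_index.py`), the shuffling test (`03_shuffling_test.py`)
and gene-set overlaps with the Ochiai/UPGMA similarity tree
(`05_gene_set_overlaps.py`). A thin CLI (`phylostress simulate | pai | di |
permtest | netstats | run-all`) exposes the same stages on TSV/FASTA/OBO
files.

## Layout

```
src/phylostress/
  taxonomy.py            lineage model, single-child collapse, divergence ranks
  phylostratigraphy.py   PAI assignment and age distributions
  divergence.py          NG86 Ka/Ks, DI classification, bins, quantiles, census
  gene_sets.py           keyword/evidence set construction, Ochiai, UPGMA
  resampling.py          shuffling test, chi-square, exhaustive oracle
  network_analysis.py    filtering, cluster quality, assortativity, |dPAI|
  function_evolution.py  hypergeometric+BH enrichment, term age profiles
  synthetic_data.py      generators with truth tables
  io.py / pipeline.py / cli.py   formats, orchestration, CLI
```

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical conventions.
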