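# Methods

## Lineage model and PAI

The focal species' evolutionary history is modelled as a linear chain of
phylostrata (internodes), each carrying an integer rank — the PAI a gene
founded there receives — and the set of species whose lineages diverge at
that internode. Full bifurcating phylogenies are represented only through
this species→stratum assignment, which is sufficient for age indexing: the
divergence rank of a subject species is the rank of its stratum, i.e. the
most basal taxon it shares with the focal lineage.

Internodes with a single daughter taxon carry no resolution and can be
collapsed. Two renumbering conventions are supported: `keep_ranks` leaves
surviving ranks untouched (gaps allowed), keeping previously published PAI
values directly comparable — this is the default — and `compact_ranks`
renumbers the survivors 0..K−1 (an 18-level chain with three internal
drops ends with terminal rank 14). Species of a dropped stratum are
reassigned to its parent (root-ward neighbour), which preserves the
basal-most-shared-taxon semantics; a dropped root's species go to the new
root, the only stratum that can absorb them.

A gene's PAI is the minimum divergence rank over its ortholog hits with
identity at or above the threshold. The cutoff is inclusive (a hit exactly
at 0.5 survives at threshold 0.5); the choice is documented here because
published descriptions of identity cutoffs rarely state it. Genes with no
surviving non-focal hit are treated as focal-species-specific and take the
terminal rank rather than being dropped, since the youngest phylostratum
*is* the focal species. Raising the threshold can only remove hits, so it
never decreases a PAI (a property test enforces this).

## Divergence index

Ka and Ks are estimated with Nei–Gojobori (1986) counting under the
universal genetic code:

* **Sites.** For each codon, each position contributes the fraction of its
  three possible single-nucleotide changes that are synonymous; changes
  producing a stop codon count as nonsynonymous. Site totals are averaged
  over the two sequences.
* **Differences.** For codon pairs differing at d positions, synonymous and
  nonsynonymous step counts are averaged over all d! orderings of the
  changes, excluding orderings that pass through a stop codon (with a
  fallback to all orderings in the rare case every path is blocked).
* **Correction.** Each proportion p is corrected for multiple hits with
  Jukes–Cantor, d = −3/4·ln(1 − 4p/3). Proportions at or beyond the
  singularity (p ≥ 3/4) are flagged `saturated`; pairs with Ks = 0 are
  flagged `excluded_ks_zero`, since a ratio with a zero denominator carries
  no information about relative rates.

All 61×61 pairwise codon quantities are precomputed into lookup tables at
import, so genome-scale scans are table lookups. Alignments are inputs:
the package validates (equal length, multiple of 3, ACGT only, no internal
stops) but never aligns.

Classification: DI > 1 → positive selection; DI within `neutral_tolerance`
(default 0.05) *below* 1 → neutral; DI = 0 → strong purifying (its own
class by default); otherwise purifying. The neutral band deliberately does
not extend past 1: any excess of nonsynonymous over synonymous divergence
is reported as positive, matching the convention under which marginal
values such as 1.02 are called positively selected.

DI histograms use eleven bins — [0, 0.1] closed, then (0.1, 0.2] …
(0.9, 1], then (1, +∞) — so that the boundary value 0.1 falls in the first
bin and 1.0 in the last finite one. Quantiles use numpy's linear
interpolation.

## Gene sets

Term selection is case-insensitive substring matching of a keyword over
term names and definitions, followed by the full is_a descendant closure;
`part_of` and other relations are ignored. Manual curation cannot be
automated, so it is represented by an explicit exclusion list applied
*after* the closure — excluding a matched parent does not silently drop
its children. Gene membership requires an annotation to a selected term
with experimental evidence (IDA/IMP/IGI/IPI by default).

Pairwise similarity uses the Ochiai coefficient |A∩B|/√(|A||B|); overlap
tables report symmetric shared counts and row-normalised (hence
asymmetric) fractions, per-set unique genes, and a pooled non-redundant
union set. Set clustering is UPGMA with merge height = average pairwise
distance / 2 (leaf-to-root depth is half the cophenetic distance, and the
tree is ultrametric by construction); among tied minimal pairs the
lexicographically smallest label pair merges first, making topologies
deterministic. scipy's average-linkage serves as the independent oracle in
tests.

## Shuffling test

For a stress set of size m against a background of N values (PAI ranks or
DI reals), each of N_perm replicates draws m values without replacement
and computes the mean, the chi-square of binned counts against background
frequencies (bins with zero background frequency are excluded from the sum
but their observed counts still count toward m), and the per-bin frequency
difference. For each statistic, n_rand counts replicates whose value
*strictly* exceeds the observed one (ties count as non-exceeding); the
p-value is exactly n_rand/N_perm with no +1 correction, so p = 0 must be
read as "< 1/N_perm". Both tails are flagged at α and 1−α, because an
observed statistic can be either unusually large (p small) or unusually
small (p near 1, e.g. a stress set far older than any random draw, which
reports the full count N_perm). The prose interpretation of which tail
means "older" is left to the caller; the package reports raw counts and
flags only.

Sampling is vectorised by arg-partitioning blocks of uniform matrices;
identical seed and inputs reproduce results bit for bit. An exhaustive
enumeration over all C(N, m) subsets provides the exact reference on small
backgrounds and is the oracle the sampled test must converge to (within 3
Monte-Carlo standard errors in the tests). Under the null, with continuous
values, the p distribution over repeated experiments is uniform up to the
1/N_perm grid — the calibration test checks this by Kolmogorov–Smirnov at
α = 0.01. With heavily tied discrete statistics the strict-inequality
convention makes p sub-uniform; that is a property of the definition, not
a defect, and the calibration check therefore uses continuous values.

An alternative background restricted to genes with at least one annotation
record is available (`annotated_background`), since unannotated genes are
disproportionately young and their exclusion from keyword-built sets can
bias the comparison.

## Network statistics

Edge lists carry confidence scores in [0, 1] (STRING-style 0–1000 scores
are autodetected and rescaled). The cutoff is inclusive (score ≥ 0.7 by
default) with a `strict_gt` switch; nodes left without any retained edge
are dropped by default, and a node audit reports genes dropped from or
added to the input list.

* Cluster quality: deg_int = 2·(within-cluster edges)/|C|, deg_ext =
  (boundary edges)/|C|, compared against the network mean degree
  k_net = 2|E|/|V|. Clusters are an *input* (real delineations are
  expert judgement); a greedy-modularity helper labels synthetic demo
  networks and is explicitly a stand-in.
* Degree–age correlation: Pearson r over nodes with the two-sided t-test
  p-value; undefined (an error) when either variable is constant.
* Age assortativity: r_a is the Pearson correlation of PAI over the 2|E|
  directed edge-end pairs — the scalar/numeric assortativity of an
  undirected graph. σ(r_a) is the single-edge-deletion jack-knife,
  √(Σ_i (r_i − r_a)²); it costs O(|E|²) and can be skipped. Zero age
  variance over edge ends makes r_a undefined (flagged, not raised).
* |dPAI| by distance: exact BFS shortest paths per connected component, no
  cutoff; each unordered reachable pair contributes once to bucket 1, 2 or
  ≥3 (unordered because |dPAI| is symmetric); cross-component pairs are
  excluded.

## Enrichment and term age profiles

Term over-representation is the hypergeometric upper tail
P(X ≥ k_set) with Benjamini–Hochberg FDR across tested terms (only terms
annotating ≥ 1 set gene are tested). This is a deterministic, dependency-free
replacement for service-based enrichment tools; EASE-style penalised scores
would be slightly more conservative. Term × age profiles count directly
annotated genes within the given gene scope (typically one stress
network's list), normalise to 100% exactly (rounding drift is folded into
the last bin at double precision), and report the minimum rank present as
the acquisition stratum.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, at
desk scale, with every truth table returned:

* **Taxonomy**: 15 phylostrata by default (an 18-internode chain with
  three single-daughter levels removed), 3 species per stratum.
* **Birth ranks**: tri-modal default distribution (≈50% of genes at ranks
  0–1, secondary peaks mid-lineage and near rank 12, ≈6% terminal),
  echoing the shape of real plant phylostratigraphic profiles with their
  whole-genome-duplication peaks.
* **Ortholog detection**: a gene born at rank b has a potential hit in
  every species diverging at rank ≥ b; hits are missed independently with
  probability `detection_noise` (default 0.05) and carry identity
  clip(1 − 0.04·depth + N(0, 0.05²)), placing the deepest orthologs near
  identity 0.45 so the 0.5/0.6/0.7 thresholds genuinely bite. Misses can
  only age a gene upward — estimated PAI ≥ true birth rank always.
* **Codon pairs**: ancestor codons uniform over the 61 sense codons; each
  descendant accumulates Poisson(3·L·t) single-nucleotide proposals
  (default t = 0.15 per site per lineage), accepted with probability 1 if
  synonymous, ω if nonsynonymous, 0 if stop-producing. This
  proposal–acceptance scheme is not a full codon-model matrix; its
  guarantee is the limit behaviour (mean estimated DI within 15% of ω for
  ω ∈ {0.2, 1}, checked over 50 replicates of 3,000 codons). Under ω = 0
  the amino-acid sequence is invariant, but NG86 may still count a
  residual Ka when synonymous paths cross codon groups (Ser/Leu/Arg) — a
  property of the estimator.
* **Networks**: edges drawn without replacement with weight
  exp(−β·|dPAI|); β = 0 gives an Erdős–Rényi-like null (r_a ≈ 0), the
  default β = 0.5 plants recoverable positive assortativity; scores are
  uniform on [0.7, 1] so the default filter keeps everything.
* **Stress sets**: seven sets with the published sizes (102–231 genes) and
  exact published pairwise shared-gene counts, realised as dedicated
  pairwise blocks (higher-order intersections are zero by construction —
  real sets overlap at third order too, which this design deliberately
  does not reproduce). The emitted ontology and IDA-coded annotations
  round-trip: keyword selection + evidence filtering rebuilds every
  planted set exactly, with IEA decoys exercising the evidence filter.

What passing tests on these data do **not** show: robustness to alignment
error, paralog confusion or annotation bias in real resources; the
generators have no gene duplication, loss, synteny or rate heterogeneity.

## Problem sizes and numerical choices

Test and demo runs use 400–5,000-gene backgrounds, 2,000–100,000
permutations, 150–200-edge networks and 50-replicate codon simulations —
sizes chosen so the full suite completes in seconds while keeping
Monte-Carlo standard errors well inside the asserted tolerances. Frequency
profiles validate Σf = 1 to 1e−12; term profiles validate Σ% = 100 to
1e−9; chi-square excludes zero-expectation bins with a logged warning.
Degenerate inputs (empty collections, constant variables, single edges,
Ks = 0) raise typed errors or return flagged undefined values as described
above, never silent NaNs.

## Known limitations

The min-over-hits PAI reading treats every hit species independently
(no ortholog-cluster reconstruction); NG86 is a counting estimator and
underestimates ω > 1 at high divergence; UPGMA assumes ultrametricity that
set-similarity data need not satisfy; enrichment treats annotations as
independent; and the planted overlap design reproduces pairwise but not
higher-order set intersections.
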