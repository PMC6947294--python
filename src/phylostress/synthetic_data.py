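"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is deterministic under a fixed seed and returns its truth
table (birth ranks, simulated omega, planted assortativity, planted
overlaps) so that each downstream estimator has a recovery test.  The
emulated structure:

* a linear phylostratum chain with species assigned to each internode;
* ortholog detection in which a gene born at rank b has a potential hit in
  every species diverging at rank >= b, realised with probability
  1 - detection_noise, with percent identity decaying in divergence depth
  plus Gaussian noise (misses can only age a gene upward, never downward);
* coding-sequence pairs evolved from a common ancestor by per-site
  nucleotide proposals accepted with probability 1 if synonymous and omega
  if nonsynonymous (stop-producing proposals rejected), so the realised
  dN/dS approaches omega in the long-sequence limit;
* interaction networks with edge probability proportional to
  exp(-beta * |dPAI|): beta = 0 is an Erdos-Renyi-like null, beta > 0
  plants positive age assortativity;
* stress gene sets with exact planted pairwise intersections, plus an
  ontology and evidence-coded annotations from which the keyword-driven
  set construction rebuilds them verbatim.

Default sizes follow the study conditions this package emulates: 15
phylostrata, stress-set sizes 102-231 with the published pairwise overlap
counts, interaction networks of ~100-220 edges, identity scores centred so
that the deepest orthologs straddle the 0.5 detection threshold.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from phylostress.divergence import AMINO_ACID, STOP_CODONS, CodonPairAlignment
from phylostress.gene_sets import AnnotationRecord, OntologyTerm, StressGeneSet
from phylostress.network_analysis import AgeNetwork, filter_network
from phylostress.taxonomy import Lineage, Phylostratum

_BASES = "ACGT"
_SENSE_CODONS = sorted(c for c in AMINO_ACID if c not in STOP_CODONS)


def _default_birth_distribution(n_strata: int) -> tuple:
    """Tri-modal age distribution: ~half the genes ancient (ranks 0-1), a
    secondary peak mid-lineage and a younger peak, echoing the shape of
    real plant phylostratigraphic profiles."""
    w = np.full(n_strata, 1.0)
    w[0] = 14.0
    if n_strata > 1:
        w[1] = 10.0
    mid = round(n_strata * 0.45)
    young = round(n_strata * 0.8)
    if 1 < mid < n_strata:
        w[mid] = 7.0
    if 1 < young < n_strata:
        w[young] = 4.0
    w[-1] = 3.0
    return tuple(w / w.sum())


#: Published stress-set sizes and pairwise shared-gene counts used as the
#: default planted overlap design (salt size follows the in-text count 231).
DEFAULT_SET_SIZES = {
    "cold": 150,
    "heat": 102,
    "light": 155,
    "osmotic": 117,
    "oxidative": 154,
    "salt": 231,
    "water": 216,
}
DEFAULT_OVERLAPS = {
    ("cold", "heat"): 8,
    ("cold", "light"): 9,
    ("cold", "osmotic"): 17,
    ("cold", "oxidative"): 6,
    ("cold", "salt"): 18,
    ("cold", "water"): 18,
    ("heat", "light"): 8,
    ("heat", "osmotic"): 8,
    ("heat", "oxidative"): 6,
    ("heat", "salt"): 13,
    ("heat", "water"): 11,
    ("light", "osmotic"): 3,
    ("light", "oxidative"): 6,
    ("light", "salt"): 7,
    ("light", "water"): 12,
    ("osmotic", "oxidative"): 12,
    ("osmotic", "salt"): 47,
    ("osmotic", "water"): 29,
    ("oxidative", "salt"): 18,
    ("oxidative", "water"): 11,
    ("salt", "water"): 41,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic-data generators (defaults = study conditions)."""

    n_strata: int = 15
    species_per_stratum: int = 3
    n_genes: int = 5000
    birth_distribution: tuple = None
    detection_noise: float = 0.05
    identity_slope: float = 0.04   # identity loss per stratum of divergence depth
    identity_noise: float = 0.05   # s.d. of Gaussian identity noise
    omega_classes: dict = field(
        default_factory=lambda: {
            "purifying": (0.2, 0.85),
            "neutral": (1.0, 0.135),
            "positive": (2.0, 0.015),
        }
    )
    n_codons: int = 300
    branch_length: float = 0.15    # proposals per nucleotide site per lineage
    n_edges: int = 200
    assortativity_strength: float = 0.5  # beta in exp(-beta * |dPAI|)
    set_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SET_SIZES))
    overlaps: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAPS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strata < 2:
            raise ValueError("need at least 2 strata (root and focal terminal)")
        if self.birth_distribution is None:
            self.birth_distribution = _default_birth_distribution(self.n_strata)
        p = np.asarray(self.birth_distribution, dtype=float)
        if p.size != self.n_strata or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("birth_distribution must be a probability vector over ranks")
        probs = [q for _, q in self.omega_classes.values()]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("omega class probabilities must sum to 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_taxonomy(config: SimulationConfig, rng=None):
    """A linear phylostratum chain with species tables.

    Returns (Lineage, species DataFrame with columns species_id,
    stratum_name, rank).  The terminal stratum holds the focal species plus
    ``species_per_stratum - 1`` close relatives.
    """
    if config.species_per_stratum < 1:
        raise ValueError("species_per_stratum must be >= 1 (terminal needs the focal species)")
    strata = []
    rows = []
    focal = "focal_sp"
    for rank in range(config.n_strata):
        name = f"PS{rank:02d}"
        species = {f"sp_r{rank:02d}_{i}" for i in range(config.species_per_stratum)}
        if rank == config.n_strata - 1:
            species = set(itertools.islice(species, config.species_per_stratum - 1))
            species.add(focal)
        for sp in sorted(species):
            rows.append((sp, name, rank))
        strata.append(Phylostratum(name=name, rank=rank, species=frozenset(species)))
    lineage = Lineage(tuple(strata), focal_species=focal)
    table = pd.DataFrame(rows, columns=["species_id", "stratum_name", "rank"])
    return lineage, table


def simulate_ortholog_hits(config: SimulationConfig, lineage: Lineage, rng=None):
    """Ortholog-hit table plus the true birth-rank table.

    A gene born at rank b has a potential hit in every non-focal species
    whose divergence rank is >= b; each hit is realised with probability
    1 - detection_noise and carries identity
    clip(1 - identity_slope * (terminal_rank - r) + noise, 0, 1).
    """
    rng = config.rng() if rng is None else rng
    ranks = np.array(lineage.ranks)
    births = rng.choice(ranks, size=config.n_genes, p=np.asarray(config.birth_distribution))
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])
    terminal = lineage.terminal_rank

    frames = []
    for stratum in lineage.strata:
        for sp in sorted(stratum.species):
            if sp == lineage.focal_species:
                continue
            mask = births <= stratum.rank
            n = int(mask.sum())
            if n == 0:
                continue
            detected = rng.random(n) < 1.0 - config.detection_noise
            if not detected.any():
                continue
            sub = genes[mask][detected]
            ident = np.clip(
                1.0
                - config.identity_slope * (terminal - stratum.rank)
                + rng.normal(0.0, config.identity_noise, size=sub.size),
                0.0,
                1.0,
            )
            frames.append(
                pd.DataFrame(
                    {"gene_id": sub, "species_id": sp, "identity": ident}
                )
            )
    hits = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene_id", "species_id", "identity"])
    )
    truth = pd.DataFrame({"gene_id": genes, "birth_rank": births})
    return hits, truth


def _evolve_sequence(codons: list, n_proposals: int, omega: float, rng) -> list:
    """Evolve a codon list by accept/reject single-nucleotide proposals."""
    codons = list(codons)
    n_sites = 3 * len(codons)
    if n_proposals == 0:
        return codons
    sites = rng.integers(0, n_sites, size=n_proposals)
    base_choices = rng.integers(0, 3, size=n_proposals)
    accept_draws = rng.random(n_proposals)
    for site, b_idx, u in zip(sites, base_choices, accept_draws):
        ci, pos = divmod(int(site), 3)
        codon = codons[ci]
        current = codon[pos]
        alternatives = [b for b in _BASES if b != current]
        new_base = alternatives[b_idx]
        mutant = codon[:pos] + new_base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        if AMINO_ACID[mutant] == AMINO_ACID[codon]:
            codons[ci] = mutant           # synonymous: always accepted
        elif u < omega:
            codons[ci] = mutant           # nonsynonymous: accepted w.p. omega
    return codons


def simulate_codon_pairs(
    config: SimulationConfig,
    n_pairs: int = None,
    omega: float = None,
    rng=None,
):
    """Aligned gap-free codon pairs evolved under a chosen (or drawn) omega.

    Each pair descends from a random sense-codon ancestor; both copies
    accumulate Poisson(branch_length * 3 * n_codons) mutation proposals.
    When ``omega`` is None, each gene draws its omega from
    ``config.omega_classes``.  Returns (list of CodonPairAlignment, truth
    DataFrame with gene_id, omega, class).
    """
    rng = config.rng() if rng is None else rng
    if config.n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    n_pairs = config.n_genes if n_pairs is None else n_pairs
    class_names = list(config.omega_classes)
    class_probs = [config.omega_classes[c][1] for c in class_names]
    alignments = []
    truth_rows = []
    for i in range(n_pairs):
        if omega is None:
            cls = class_names[rng.choice(len(class_names), p=class_probs)]
            w = config.omega_classes[cls][0]
        else:
            cls, w = "fixed", float(omega)
        ancestor = [
            _SENSE_CODONS[k]
            for k in rng.integers(0, len(_SENSE_CODONS), size=config.n_codons)
        ]
        n_prop = 3 * config.n_codons * config.branch_length
        a = _evolve_sequence(ancestor, rng.poisson(n_prop), w, rng)
        b = _evolve_sequence(ancestor, rng.poisson(n_prop), w, rng)
        gene = f"g{i:05d}"
        alignments.append(
            CodonPairAlignment(gene=gene, seq_focal="".join(a), seq_relative="".join(b))
        )
        truth_rows.append((gene, w, cls))
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "omega", "class"])
    return alignments, truth


def simulate_network(config: SimulationConfig, ages: dict, rng=None) -> AgeNetwork:
    """Gene network with planted age assortativity.

    Edges are drawn without replacement from all node pairs with weight
    exp(-beta * |dPAI|); scores are uniform on [0.7, 1] so every edge
    passes the default confidence filter.
    """
    rng = config.rng() if rng is None else rng
    nodes = sorted(ages)
    pairs = list(itertools.combinations(nodes, 2))
    if config.n_edges > len(pairs):
        raise ValueError(
            f"cannot place {config.n_edges} edges among {len(pairs)} node pairs"
        )
    beta = config.assortativity_strength
    dpai = np.array([abs(ages[a] - ages[b]) for a, b in pairs], dtype=float)
    w = np.exp(-beta * dpai)
    chosen = rng.choice(len(pairs), size=config.n_edges, replace=False, p=w / w.sum())
    scores = rng.uniform(0.7, 1.0, size=config.n_edges)
    edges = [(*pairs[int(k)], float(s)) for k, s in zip(chosen, scores)]
    return filter_network(edges, ages, threshold=0.7, drop_isolated=True)


def simulate_stress_sets(config: SimulationConfig, genes, rng=None):
    """Stress gene sets with exact planted pairwise intersections.

    Each planted pairwise overlap is realised as a dedicated block of genes
    shared by exactly that pair (higher-order intersections are zero by
    construction), then each set is filled with unique genes to its target
    size.  Alongside the sets, an ontology and evidence-coded annotations
    are emitted such that ``select_terms_by_keyword`` (keyword = stress
    name) followed by ``build_stress_gene_set`` reproduces every planted
    set exactly; IEA-evidence decoy annotations exercise the evidence
    filter.

    Returns (sets, planted overlap DataFrame, ontology terms, annotations).
    """
    rng = config.rng() if rng is None else rng
    names = sorted(config.set_sizes)
    sizes = config.set_sizes
    overlaps = {tuple(sorted(k)): v for k, v in config.overlaps.items()}
    for (a, b), v in overlaps.items():
        if a not in sizes or b not in sizes:
            raise ValueError(f"overlap refers to unknown set(s): {(a, b)}")
        if v < 0:
            raise ValueError(f"negative planted overlap for {(a, b)}")
    committed = {
        n: sum(v for pair, v in overlaps.items() if n in pair) for n in names
    }
    for n in names:
        if committed[n] > sizes[n]:
            raise ValueError(
                f"infeasible design: set {n!r} needs {committed[n]} shared genes "
                f"but has size {sizes[n]}"
            )
    pool = list(genes)
    needed = sum(overlaps.values()) + sum(
        sizes[n] - committed[n] for n in names
    )
    if needed > len(pool):
        raise ValueError(
            f"gene pool of {len(pool)} too small for design needing {needed} genes"
        )
    order = rng.permutation(len(pool))
    consumed = 0

    def remaining():
        return len(pool) - consumed

    def take(k):
        nonlocal consumed
        if k > remaining():
            raise ValueError("gene pool exhausted during set construction")
        out = [pool[j] for j in order[consumed : consumed + k]]
        consumed += k
        return out

    members = {n: set() for n in names}
    for pair in sorted(overlaps):
        block = take(overlaps[pair])
        for n in pair:
            members[n].update(block)
    for n in names:
        members[n].update(take(sizes[n] - committed[n]))

    ontology = [
        OntologyTerm(
            id="T:stress_root",
            name="response to stress",
            definition="any process resulting from a disturbance stimulus",
        )
    ]
    annotations = []
    sets = []
    for n in names:
        parent_id = f"T:{n}"
        child_id = f"T:{n}:resp"
        ontology.append(
            OntologyTerm(
                id=parent_id,
                name=f"response to {n} stress",
                definition=f"a process in response to a {n} stimulus",
                parents=frozenset({"T:stress_root"}),
            )
        )
        ontology.append(
            OntologyTerm(
                id=child_id,
                name=f"cellular response process ({n})",
                definition=f"cellular changes following {n} exposure",
                parents=frozenset({parent_id}),
            )
        )
        member_list = sorted(members[n])
        for i, g in enumerate(member_list):
            term = parent_id if i % 2 == 0 else child_id
            annotations.append(AnnotationRecord(gene=g, term=term, evidence="IDA"))
        # decoys: electronically inferred annotations must not admit genes
        decoys = take(min(5, remaining()))
        for g in decoys:
            annotations.append(AnnotationRecord(gene=g, term=parent_id, evidence="IEA"))
        sets.append(
            StressGeneSet(
                stress=n,
                genes=frozenset(member_list),
                terms=frozenset({parent_id, child_id}),
            )
        )
    planted = pd.DataFrame(0, index=names, columns=names, dtype=int)
    for n in names:
        planted.loc[n, n] = sizes[n]
    for (a, b), v in overlaps.items():
        planted.loc[a, b] = v
        planted.loc[b, a] = v
    return sets, planted, ontology, annotations
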