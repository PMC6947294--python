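"""Stress gene-set construction from ontology keywords and annotations.

A stress gene set is built in two steps mirroring common GO-based curation:
(1) select every ontology term whose name or definition contains a keyword,
take the full is_a descendant closure, and subtract an explicit manual
exclusion list; (2) collect genes annotated to any selected term with an
experimental evidence code (IDA/IMP/IGI/IPI by default).  Pairwise set
similarity uses the Ochiai coefficient and the sets are clustered with
UPGMA.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_EVIDENCE_WHITELIST = frozenset({"IDA", "IMP", "IGI", "IPI"})


@dataclass(frozen=True)
class OntologyTerm:
    id: str
    name: str
    definition: str = ""
    parents: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "parents", frozenset(self.parents))


@dataclass(frozen=True)
class AnnotationRecord:
    gene: str
    term: str
    evidence: str


@dataclass(frozen=True)
class StressGeneSet:
    stress: str
    genes: frozenset
    terms: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        object.__setattr__(self, "terms", frozenset(self.terms))

    def __len__(self) -> int:
        return len(self.genes)


def _check_acyclic(terms) -> None:
    # Kahn's algorithm over is_a edges; leftover nodes indicate a cycle
    children: dict = {t.id: [] for t in terms}
    indeg = {t.id: 0 for t in terms}
    for t in terms:
        for p in t.parents:
            if p in children:
                children[p].append(t.id)
                indeg[t.id] += 1
    queue = deque([t for t, d in indeg.items() if d == 0])
    seen = 0
    while queue:
        node = queue.popleft()
        seen += 1
        for c in children[node]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if seen != len(indeg):
        raise ValueError("ontology is_a graph contains a cycle")


def select_terms_by_keyword(ontology, keyword: str, exclusions=frozenset()) -> frozenset:
    """Terms matching a keyword plus their full is_a descendant closure.

    Matching is case-insensitive substring search over name and definition.
    The closure is taken before subtracting ``exclusions`` (the manual
    curation list), so excluding a matched parent does not silently drop
    its unexcluded children.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    terms = list(ontology)
    _check_acyclic(terms)
    needle = keyword.lower()
    matched = {
        t.id for t in terms if needle in t.name.lower() or needle in t.definition.lower()
    }
    children: dict = {}
    for t in terms:
        for p in t.parents:
            children.setdefault(p, set()).add(t.id)
    closure = set(matched)
    queue = deque(matched)
    while queue:
        node = queue.popleft()
        for c in children.get(node, ()):
            if c not in closure:
                closure.add(c)
                queue.append(c)
    result = frozenset(closure - set(exclusions))
    if not result:
        logger.info("keyword %r selected no terms after exclusions", keyword)
    return result


def build_stress_gene_set(
    annotations,
    terms,
    name: str = "",
    evidence_whitelist=DEFAULT_EVIDENCE_WHITELIST,
) -> StressGeneSet:
    """Genes annotated to any selected term with whitelisted evidence."""
    terms = frozenset(terms)
    whitelist = frozenset(evidence_whitelist)
    genes = {
        a.gene for a in annotations if a.term in terms and a.evidence in whitelist
    }
    if not genes:
        logger.warning("gene set %r is empty after evidence filtering", name)
    return StressGeneSet(stress=name, genes=frozenset(genes), terms=terms)


def merge_sets(a: StressGeneSet, b: StressGeneSet, name: str) -> StressGeneSet:
    """Union of two stress sets under a new name (e.g. water + drought)."""
    return StressGeneSet(stress=name, genes=a.genes | b.genes, terms=a.terms | b.terms)


def overlap_stats(sets) -> dict:
    """Pairwise overlap counts and row-normalised fractions of gene sets.

    Returns a dict with:

    ``counts``
        symmetric DataFrame; diagonal holds set sizes.
    ``fractions``
        DataFrame; entry (i, j) = |G_i & G_j| / |G_i| — row-normalised and
        hence asymmetric.
    ``unique``
        Series; genes of each set found in no other set.
    ``union``
        StressGeneSet pooling all sets non-redundantly ("all stresses nr").
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("overlap_stats needs at least two sets")
    names = [s.stress for s in sets]
    n = len(sets)
    counts = np.zeros((n, n), dtype=int)
    fractions = np.zeros((n, n), dtype=float)
    for i, si in enumerate(sets):
        for j, sj in enumerate(sets):
            shared = len(si.genes & sj.genes)
            counts[i, j] = shared
            fractions[i, j] = shared / len(si.genes) if si.genes else math.nan
    unique = {}
    for i, si in enumerate(sets):
        others = set().union(*(s.genes for j, s in enumerate(sets) if j != i))
        unique[si.stress] = len(si.genes - others)
    union_genes = frozenset().union(*(s.genes for s in sets))
    union_terms = frozenset().union(*(s.terms for s in sets))
    return {
        "counts": pd.DataFrame(counts, index=names, columns=names),
        "fractions": pd.DataFrame(fractions, index=names, columns=names),
        "unique": pd.Series(unique, name="unique_genes"),
        "union": StressGeneSet(stress="all stresses nr", genes=union_genes, terms=union_terms),
    }


def ochiai_distance(a, b) -> float:
    """1 - |A & B| / sqrt(|A| * |B|): a cosine-type set dissimilarity."""
    a, b = set(a), set(b)
    if not a or not b:
        raise ValueError("Ochiai distance is undefined for empty sets")
    return 1.0 - len(a & b) / math.sqrt(len(a) * len(b))


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted ultrametric tree with heights."""

    name: str
    height: float
    children: tuple = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick(parent_height=None) + ";"

    def _newick(self, parent_height) -> str:
        if self.is_leaf:
            label = self.name
        else:
            inner = ",".join(c._newick(self.height) for c in self.children)
            label = f"({inner})"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:.6g}"


def upgma_tree(distances: pd.DataFrame) -> TreeNode:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Merge height is half the average pairwise distance between the joined
    clusters, so leaf-to-root path lengths equal half the cophenetic
    distance and the result is ultrametric.  Ties are broken by
    lexicographic order of the (smallest-leaf) cluster labels, making the
    topology deterministic.
    """
    labels = list(distances.index)
    if list(distances.columns) != labels:
        raise ValueError("distance matrix must have identical row and column labels")
    d = distances.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    if len(labels) == 1:
        return TreeNode(labels[0], 0.0)

    clusters = {
        lab: {"node": TreeNode(lab, 0.0), "size": 1, "key": lab} for lab in labels
    }
    dist = {
        frozenset((a, b)): d[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(clusters[m]["key"] for m in kv[0]))),
        )
        pair, dmin = best
        a, b = sorted(pair, key=lambda m: clusters[m]["key"])
        ca, cb = clusters.pop(a), clusters.pop(b)
        height = dmin / 2.0
        merged_key = min(ca["key"], cb["key"])
        node = TreeNode(merged_key, height, (ca["node"], cb["node"]))
        new = {"node": node, "size": ca["size"] + cb["size"], "key": merged_key}
        # UPGMA update: size-weighted average of distances to the two parts
        for other in list(clusters):
            da = dist.pop(frozenset((a, other)))
            db = dist.pop(frozenset((b, other)))
            dist[frozenset((merged_key, other))] = (
                ca["size"] * da + cb["size"] * db
            ) / (ca["size"] + cb["size"])
        del dist[pair]
        clusters[merged_key] = new
    return next(iter(clusters.values()))["node"]
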