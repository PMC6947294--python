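"""Term enrichment of gene sets and GO-term age profiles.

Enrichment is the standard hypergeometric over-representation test with
Benjamini-Hochberg control of the false discovery rate across the tested
terms (a deterministic, self-contained approximation of service-based
enrichment tools, whose EASE-style scores differ slightly).  A term age
profile gives, for one term, the percentage of its annotated genes founded
at each phylostratum, normalised to 100%; the minimum rank present is the
acquisition stratum — the evolutionary stage at which the network's gene
complement first carried that function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class TermAgeProfile:
    term: str
    freq: dict  # rank -> percentage, sums to 100
    n_genes: int
    acquisition_rank: int

    def __post_init__(self) -> None:
        if abs(sum(self.freq.values()) - 100.0) > 1e-9:
            raise ValueError("term age profile percentages must sum to 100")


def enrich_terms(set_genes, background, annotations, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in a gene set.

    Parameters
    ----------
    set_genes : genes of interest (must be a subset of ``background``)
    background : the gene universe
    annotations : iterable of AnnotationRecord (evidence is not re-filtered
        here; pass pre-filtered records if a whitelist applies)
    alpha : FDR level for the ``significant`` flag

    Returns a DataFrame with columns term, k_set, n_set, k_bg, n_bg, p_raw,
    p_adj, significant, sorted by p_adj then term.  Only terms annotating
    at least one set gene are tested.
    """
    set_genes = set(set_genes)
    background = set(background)
    if not set_genes:
        raise ValueError("gene set must be non-empty")
    if not set_genes <= background:
        raise ValueError("gene set must be a subset of the background")
    term_genes: dict = {}
    for a in annotations:
        if a.gene in background:
            term_genes.setdefault(a.term, set()).add(a.gene)
    n_bg, n_set = len(background), len(set_genes)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k_set = len(genes & set_genes)
        if k_set == 0:
            continue
        k_bg = len(genes)
        # P(X >= k_set) for X ~ Hypergeom(n_bg, k_bg, n_set)
        p_raw = float(hypergeom.sf(k_set - 1, n_bg, k_bg, n_set))
        rows.append((term, k_set, n_set, k_bg, n_bg, min(p_raw, 1.0)))
    frame = pd.DataFrame(
        rows, columns=["term", "k_set", "n_set", "k_bg", "n_bg", "p_raw"]
    )
    if frame.empty:
        frame["p_adj"] = []
        frame["significant"] = []
        return frame
    reject, p_adj, _, _ = multipletests(frame["p_raw"], alpha=alpha, method="fdr_bh")
    frame["p_adj"] = p_adj
    frame["significant"] = reject
    return frame.sort_values(["p_adj", "term"]).reset_index(drop=True)


def term_age_profile(term: str, ages: dict, annotations) -> TermAgeProfile:
    """Age distribution (in %) of the genes annotated with one term.

    ``ages`` maps gene -> PAI for the gene scope of interest (typically one
    stress network's gene list); only directly annotated genes present in
    that scope are counted.
    """
    genes = {a.gene for a in annotations if a.term == term and a.gene in ages}
    if not genes:
        raise ValueError(f"no gene in scope is annotated with term {term!r}")
    ranks = np.array(sorted(ages[g] for g in genes))
    labels, counts = np.unique(ranks, return_counts=True)
    freq = {int(r): 100.0 * c / len(genes) for r, c in zip(labels, counts)}
    # exact-100 normalisation against rounding drift
    drift = 100.0 - sum(freq.values())
    if freq and abs(drift) > 0:
        last = max(freq)
        freq[last] += drift
    return TermAgeProfile(
        term=term,
        freq=freq,
        n_genes=len(genes),
        acquisition_rank=int(labels.min()),
    )
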