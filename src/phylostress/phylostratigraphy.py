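"""Gene age assignment (PAI) from identity-filtered ortholog hits.

The phylostratigraphic age index of a gene is the rank of the most basal
lineage internode shared with any species in which an ortholog is detected
at or above the identity threshold.  Genes with no surviving hit outside
the focal species fall in the terminal (focal-species-specific) stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phylostress.taxonomy import Lineage

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OrthologHit:
    """A detected homolog of one focal gene in one subject species."""

    gene: str
    species: str
    identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity must be in [0, 1], got {self.identity}")


@dataclass(frozen=True)
class GeneAgeRecord:
    gene: str
    pai: int


@dataclass(frozen=True)
class FrequencyProfile:
    """Counts and relative frequencies over an ordered sequence of bins."""

    bins: tuple
    counts: tuple
    freq: tuple

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.counts) or len(self.bins) != len(self.freq):
            raise ValueError("bins, counts and freq must have equal length")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")
        if self.total > 0 and abs(sum(self.freq) - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def from_counts(cls, bins, counts) -> "FrequencyProfile":
        counts = tuple(int(c) for c in counts)
        total = sum(counts)
        if total == 0:
            raise ValueError("cannot build a frequency profile from zero counts")
        freq = tuple(c / total for c in counts)
        return cls(tuple(bins), counts, freq)


def assign_pai(hits, identity_threshold: float, lineage: Lineage) -> GeneAgeRecord:
    """Assign the PAI of one gene from its ortholog hits.

    PAI is the minimum divergence rank over hits whose identity is at or
    above the threshold (the cutoff is inclusive).  With no surviving hit
    outside the focal species the gene is focal-species-specific and gets
    the terminal rank.
    """
    if not 0.0 <= identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in [0, 1]")
    hits = list(hits)
    genes = {h.gene for h in hits}
    if len(genes) > 1:
        raise ValueError(f"assign_pai expects hits of a single gene, got {sorted(genes)}")
    if not hits:
        logger.warning("gene with no ortholog hits assigned terminal rank")
        return GeneAgeRecord(gene="", pai=lineage.terminal_rank)
    gene = hits[0].gene
    ranks = [
        lineage.species_rank(h.species)
        for h in hits
        if h.identity >= identity_threshold
    ]
    pai = min(ranks) if ranks else lineage.terminal_rank
    return GeneAgeRecord(gene=gene, pai=int(pai))


def assign_pai_table(
    hits: pd.DataFrame,
    identity_threshold: float,
    lineage: Lineage,
    all_genes=None,
) -> pd.DataFrame:
    """Vectorised PAI assignment for a whole hit table.

    Parameters
    ----------
    hits : DataFrame with columns gene_id, species_id, identity
    identity_threshold : float
    lineage : Lineage
    all_genes : optional iterable
        Genes guaranteed a row in the output; those without any surviving
        hit receive the terminal rank.

    Returns
    -------
    DataFrame with columns gene_id, pai.
    """
    if not 0.0 <= identity_threshold <= 1.0:
        raise ValueError("identity_threshold must be in [0, 1]")
    kept = hits[hits["identity"] >= identity_threshold]
    rank = kept["species_id"].map(lineage.species_rank)
    pai = rank.groupby(kept["gene_id"]).min()
    if all_genes is not None:
        pai = pai.reindex(pd.Index(all_genes, name="gene_id"))
    n_missing = int(pai.isna().sum())
    if n_missing:
        logger.warning(
            "%d gene(s) without surviving ortholog hits assigned terminal rank %d",
            n_missing,
            lineage.terminal_rank,
        )
    pai = pai.fillna(lineage.terminal_rank).astype(int)
    return pai.rename("pai").reset_index()


def pai_distribution(records, lineage: Lineage) -> FrequencyProfile:
    """Age frequency distribution over all surviving lineage ranks.

    Every rank of the lineage gets a bin, including zero-count ones, so that
    profiles from different gene sets over the same lineage line up bin for
    bin.
    """
    values = [r.pai if isinstance(r, GeneAgeRecord) else int(r) for r in records]
    if not values:
        raise ValueError("cannot build a PAI distribution from an empty collection")
    ranks = lineage.ranks
    valid = set(ranks)
    bad = sorted(set(values) - valid)
    if bad:
        raise ValueError(f"PAI value(s) {bad} not present in the lineage ranks {ranks}")
    counts = np.zeros(len(ranks), dtype=int)
    index = {r: i for i, r in enumerate(ranks)}
    for v in values:
        counts[index[v]] += 1
    return FrequencyProfile.from_counts(ranks, counts)
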