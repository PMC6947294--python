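"""Ka, Ks and the divergence index DI for focal/relative CDS pairs.

Ka and Ks (nonsynonymous and synonymous substitutions per corresponding
site) are estimated with the Nei-Gojobori (1986) counting method:

* synonymous/nonsynonymous *site* counts per codon are the per-position
  fractions of the three possible single-nucleotide changes that are
  synonymous, with changes producing a stop codon counted as nonsynonymous;
  sites are averaged over the two sequences;
* synonymous/nonsynonymous *difference* counts per codon pair are averaged
  over all mutational pathways (orderings of the differing positions),
  excluding pathways that pass through a stop codon;
* the raw proportions p = differences / sites are corrected for multiple
  hits with the Jukes-Cantor formula d = -3/4 * ln(1 - 4p/3).

DI = Ka/Ks.  Genes with Ks = 0 carry no information about relative rates
and are flagged ``excluded_ks_zero``; proportions at or beyond the
Jukes-Cantor singularity (p >= 3/4) are flagged ``saturated``.  DI < 1
indicates purifying selection, DI ~ 1 neutral evolution and DI > 1 positive
Darwinian selection.

All pairwise codon quantities are precomputed into 64x64 lookup tables at
import, so per-alignment work is a table lookup per codon pair.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from Bio.Data import CodonTable

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

_TABLE = CodonTable.unambiguous_dna_by_name["Standard"]
CODONS = ["".join(c) for c in itertools.product(_BASES, repeat=3)]
STOP_CODONS = frozenset(_TABLE.stop_codons)
AMINO_ACID = {
    c: ("*" if c in STOP_CODONS else _TABLE.forward_table[c]) for c in CODONS
}


def _codon_index(codon: str) -> int:
    return 16 * _BASE_INDEX[codon[0]] + 4 * _BASE_INDEX[codon[1]] + _BASE_INDEX[codon[2]]


def _site_counts() -> np.ndarray:
    """Per-codon synonymous site counts s(c); nonsynonymous = 3 - s(c)."""
    syn = np.full(64, np.nan)
    for codon in CODONS:
        if codon in STOP_CODONS:
            continue
        s = 0.0
        for pos in range(3):
            for b in _BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                # stop-producing changes are nonsynonymous by convention
                if mutant not in STOP_CODONS and AMINO_ACID[mutant] == AMINO_ACID[codon]:
                    s += 1.0 / 3.0
        syn[_codon_index(codon)] = s
    return syn


def _pathway_diffs(c1: str, c2: str) -> tuple:
    """Pathway-averaged (synonymous, nonsynonymous) differences for a codon pair.

    Averages over all orderings of the differing positions; orderings that
    pass through a stop codon are excluded (if every ordering is blocked,
    the average falls back to all orderings).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        current = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((current, nxt))
            current = nxt
        syn = sum(1.0 for a, b in steps if AMINO_ACID[a] == AMINO_ACID[b])
        paths.append((blocked, syn, len(steps) - syn))
    open_paths = [(s, n) for blocked, s, n in paths if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in open_paths) / len(open_paths)
    non = sum(n for _, n in open_paths) / len(open_paths)
    return syn, non


def _diff_tables() -> tuple:
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    sense = [c for c in CODONS if c not in STOP_CODONS]
    for c1 in sense:
        i = _codon_index(c1)
        for c2 in sense:
            j = _codon_index(c2)
            s, n = _pathway_diffs(c1, c2)
            sd[i, j] = s
            nd[i, j] = n
    return sd, nd


_SYN_SITES = _site_counts()
_SD, _ND = _diff_tables()


@dataclass(frozen=True)
class CodonPairAlignment:
    """A gap-free aligned coding-sequence pair for one gene.

    Both sequences must be equal length, a multiple of 3, over {A,C,G,T},
    and free of internal stop codons.
    """

    gene: str
    seq_focal: str
    seq_relative: str

    def __post_init__(self) -> None:
        a, b = self.seq_focal.upper(), self.seq_relative.upper()
        object.__setattr__(self, "seq_focal", a)
        object.__setattr__(self, "seq_relative", b)
        if len(a) != len(b):
            raise ValueError(f"{self.gene}: sequences differ in length ({len(a)} vs {len(b)})")
        if len(a) % 3 != 0:
            raise ValueError(f"{self.gene}: length {len(a)} not divisible by 3")
        if len(a) == 0:
            raise ValueError(f"{self.gene}: empty alignment")
        for seq, label in ((a, "focal"), (b, "relative")):
            bad = set(seq) - set(_BASES)
            if bad:
                raise ValueError(f"{self.gene}/{label}: non-ACGT symbol(s) {sorted(bad)}")
            for k in range(0, len(seq), 3):
                if seq[k : k + 3] in STOP_CODONS:
                    raise ValueError(
                        f"{self.gene}/{label}: internal stop codon at position {k}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.seq_focal) // 3

    def codon_indices(self) -> tuple:
        a = np.array(
            [_codon_index(self.seq_focal[k : k + 3]) for k in range(0, len(self.seq_focal), 3)]
        )
        b = np.array(
            [
                _codon_index(self.seq_relative[k : k + 3])
                for k in range(0, len(self.seq_relative), 3)
            ]
        )
        return a, b


@dataclass(frozen=True)
class DivergenceResult:
    """Ka, Ks, DI and exclusion status of one gene pair.

    status ``ok``: di = ka/ks with ks > 0; ``excluded_ks_zero``: no
    synonymous substitutions, di undefined; ``saturated``: a raw proportion
    reached the Jukes-Cantor singularity, distances undefined.
    """

    gene: str
    ka: float
    ks: float
    di: float
    status: str


def _jukes_cantor(p: float) -> float:
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) + 0.0  # +0.0 avoids -0.0


def ng86_ka_ks(alignment: CodonPairAlignment) -> DivergenceResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction."""
    ia, ib = alignment.codon_indices()
    syn_sites = 0.5 * (_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum())
    non_sites = 3.0 * alignment.n_codons - syn_sites
    syn_diffs = _SD[ia, ib].sum()
    non_diffs = _ND[ia, ib].sum()

    p_s = syn_diffs / syn_sites if syn_sites > 0 else 0.0
    p_n = non_diffs / non_sites if non_sites > 0 else 0.0
    if p_s >= 0.75 or p_n >= 0.75:
        return DivergenceResult(alignment.gene, math.nan, math.nan, math.nan, "saturated")
    ks = _jukes_cantor(p_s)
    ka = _jukes_cantor(p_n)
    if ks == 0.0:
        return DivergenceResult(alignment.gene, ka, 0.0, math.nan, "excluded_ks_zero")
    return DivergenceResult(alignment.gene, ka, ks, ka / ks, "ok")


def raw_ng86_counts(alignment: CodonPairAlignment) -> dict:
    """Uncorrected NG86 site and difference counts (diagnostic output)."""
    ia, ib = alignment.codon_indices()
    syn_sites = 0.5 * (_SYN_SITES[ia].sum() + _SYN_SITES[ib].sum())
    return {
        "syn_sites": float(syn_sites),
        "non_sites": float(3.0 * alignment.n_codons - syn_sites),
        "syn_diffs": float(_SD[ia, ib].sum()),
        "non_diffs": float(_ND[ia, ib].sum()),
    }


def classify_selection(
    result: DivergenceResult,
    zero_is_class: bool = True,
    neutral_tolerance: float = 0.05,
) -> str:
    """Selection regime implied by DI.

    DI > 1 indicates positive Darwinian selection; values just below one
    (within ``neutral_tolerance``) are called neutral; DI = 0 is strong
    purifying selection (its own class when ``zero_is_class``); everything
    else is purifying.  Any DI above 1 is positive — the neutral band does
    not extend past 1, matching the convention that even marginal excesses
    of nonsynonymous substitution are reported as positive selection.
    """
    if result.status != "ok":
        raise ValueError(
            f"cannot classify {result.gene!r}: status {result.status!r} is not 'ok'"
        )
    di = result.di
    if di > 1.0:
        return "positive"
    if di >= 1.0 - neutral_tolerance:
        return "neutral"
    if di == 0.0:
        return "purifying_strong" if zero_is_class else "purifying"
    return "purifying"


#: Eleven DI bins: [0, 0.1] then (0.1, 0.2] ... (0.9, 1] then (1, +inf).
DI_BIN_LABELS = (
    "[0, 0.1]",
    "(0.1, 0.2]",
    "(0.2, 0.3]",
    "(0.3, 0.4]",
    "(0.4, 0.5]",
    "(0.5, 0.6]",
    "(0.6, 0.7]",
    "(0.7, 0.8]",
    "(0.8, 0.9]",
    "(0.9, 1]",
    "(1, +inf)",
)

_DI_INNER_EDGES = np.arange(1, 11) / 10.0  # 0.1 .. 1.0


def di_bin(values) -> np.ndarray:
    """Counts of DI values per bin (right-closed; first bin closed at 0)."""
    values = np.asarray(list(values), dtype=float)
    if values.size and values.min() < 0:
        raise ValueError("DI values must be non-negative")
    idx = np.searchsorted(_DI_INNER_EDGES, values, side="left")
    return np.bincount(idx, minlength=len(DI_BIN_LABELS))


def di_quantiles(values, qs) -> np.ndarray:
    """Linear-interpolation quantiles of a DI collection (numpy 'linear')."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot take quantiles of an empty collection")
    qs = np.asarray(list(qs), dtype=float)
    if qs.size and (qs.min() < 0 or qs.max() > 1):
        raise ValueError("quantile fractions must lie in [0, 1]")
    return np.quantile(values, qs, method="linear")


def di_census(results) -> dict:
    """Genome-style census of divergence results.

    Returns counts and percentages (of the total) of genes excluded for
    Ks = 0, genes with DI = 0 (Ka = 0, Ks != 0) and genes with DI > 1.
    """
    results = list(results)
    total = len(results)
    if total == 0:
        raise ValueError("empty result collection")
    n_excluded = sum(1 for r in results if r.status == "excluded_ks_zero")
    ok = [r for r in results if r.status == "ok"]
    n_zero = sum(1 for r in ok if r.di == 0.0)
    n_positive = sum(1 for r in ok if r.di > 1.0)
    return {
        "total": total,
        "excluded_ks_zero": n_excluded,
        "zero_di": n_zero,
        "positive": n_positive,
        "pct_excluded_ks_zero": 100.0 * n_excluded / total,
        "pct_zero_di": 100.0 * n_zero / total,
        "pct_positive": 100.0 * n_positive / total,
    }
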