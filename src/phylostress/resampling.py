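"""Shuffling (permutation) test comparing a gene set to the genome background.

The null hypothesis is that a stress set's PAI or DI distribution is that of
a same-size sample drawn without replacement from the background.  For each
of ``n_permutations`` replicates a random same-size subset is drawn and
three families of statistics are computed: the mean value, the chi-square
deviation of the binned counts from the background frequencies, and the
per-bin frequency difference df_i = f_i(sample) - f_i(background).  For
every statistic, ``n_rand`` counts the replicates whose statistic strictly
exceeds the observed one, and the empirical p-value is exactly
p = n_rand / n_permutations (no +1 correction, so p = 0 means
"< 1/n_permutations").  Both tails are flagged: p < alpha (the observed
statistic is unusually large) and p > 1 - alpha (unusually small).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from phylostress.divergence import DI_BIN_LABELS, di_bin
from phylostress.phylostratigraphy import FrequencyProfile

logger = logging.getLogger(__name__)


class DiscreteBins:
    """Bin spec for discrete values (PAI ranks): one bin per label."""

    def __init__(self, labels):
        self.labels = tuple(labels)
        self._index = {v: i for i, v in enumerate(self.labels)}

    def count(self, values) -> np.ndarray:
        out = np.zeros(len(self.labels), dtype=int)
        for v in np.asarray(values).ravel():
            out[self._index[v]] += 1
        return out


class IntervalBins:
    """Bin spec for continuous values on the standard DI bin grid."""

    labels = DI_BIN_LABELS

    def count(self, values) -> np.ndarray:
        return di_bin(values)


@dataclass(frozen=True)
class DifferenceProfile:
    """Per-bin frequency difference between a gene set and the background."""

    bins: tuple
    df: tuple


@dataclass(frozen=True)
class ChiSquareStat:
    value: float
    bins_used: tuple


@dataclass(frozen=True)
class PermutationResult:
    """Observed statistics with exceedance counts and empirical p-values.

    ``n_rand[stat]`` is the number of replicates whose statistic strictly
    exceeded the observed value; ``p[stat] = n_rand[stat] / n_permutations``
    exactly.  ``flags[stat]`` is "low" (p < alpha), "high" (p > 1 - alpha)
    or "" per statistic; for the per-bin df statistic these are arrays.
    """

    observed: dict
    n_rand: dict
    p: dict
    flags: dict
    n_permutations: int
    seed: int
    bins: tuple = ()
    alpha: float = 0.05


def empirical_p(n_rand, n_permutations: int):
    """Empirical p-value: exactly n_rand / n_permutations (no +1 correction).

    A result of 0 therefore means "smaller than 1/n_permutations", not zero
    probability.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    return np.asarray(n_rand) / n_permutations if np.ndim(n_rand) else n_rand / n_permutations


def frequency_difference(
    stress: FrequencyProfile, background: FrequencyProfile
) -> DifferenceProfile:
    """Element-wise df_i = f_i(stress) - f_i(background)."""
    if tuple(stress.bins) != tuple(background.bins):
        raise ValueError(
            f"bin mismatch: {tuple(stress.bins)} vs {tuple(background.bins)}"
        )
    df = tuple(s - b for s, b in zip(stress.freq, background.freq))
    return DifferenceProfile(bins=tuple(stress.bins), df=df)


def chi_square_stat(observed_counts, background: FrequencyProfile) -> ChiSquareStat:
    """Chi-square of observed counts against background expected frequencies.

    Bins with zero background frequency are excluded from the sum (their
    expectation is zero); observed counts there still contribute to N and a
    warning is logged if any are non-zero.
    """
    obs = np.asarray(list(observed_counts), dtype=float)
    freq = np.asarray(background.freq, dtype=float)
    if obs.shape != freq.shape:
        raise ValueError("observed counts and background bins differ in length")
    n = obs.sum()
    if n <= 0:
        raise ValueError("observed counts must sum to a positive total")
    usable = freq > 0
    dropped_with_counts = (~usable) & (obs > 0)
    if dropped_with_counts.any():
        logger.warning(
            "%d observed count(s) fall in zero-background bins and are excluded "
            "from the chi-square sum",
            int(obs[dropped_with_counts].sum()),
        )
    expected = n * freq[usable]
    value = float(((obs[usable] - expected) ** 2 / expected).sum())
    labels = tuple(np.asarray(background.bins, dtype=object)[usable])
    return ChiSquareStat(value=value, bins_used=labels)


def _replicate_stats(sample_matrix, binning, bg_freq, want_mean, want_binned):
    """Statistics for an (R, m) matrix of sampled values."""
    out = {}
    if want_mean:
        out["mean"] = sample_matrix.mean(axis=1)
    if want_binned:
        r, m = sample_matrix.shape
        counts = np.empty((r, len(binning.labels)), dtype=float)
        for i in range(r):
            counts[i] = binning.count(sample_matrix[i])
        usable = bg_freq > 0
        expected = m * bg_freq[usable]
        out["chisq"] = ((counts[:, usable] - expected) ** 2 / expected).sum(axis=1)
        out["df"] = counts / m - bg_freq
    return out


def permutation_test(
    background_values,
    stress_indices,
    binning=None,
    statistics=("mean", "chisq", "df"),
    n_permutations: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Shuffling test of a stress subset against the full background.

    Parameters
    ----------
    background_values : 1-d array
        PAI ranks or DI values for every background gene.
    stress_indices : 1-d integer array
        Positions of the stress genes within ``background_values``.
    binning : DiscreteBins | IntervalBins | None
        Required when "chisq" or "df" statistics are requested.
    statistics : subset of {"mean", "chisq", "df"}
    n_permutations, seed, alpha : test parameters.
    """
    values = np.asarray(background_values, dtype=float)
    idx = np.asarray(stress_indices, dtype=int)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if idx.size == 0:
        raise ValueError("stress set must be non-empty")
    if idx.size > values.size:
        raise ValueError("stress set larger than the background")
    if idx.min() < 0 or idx.max() >= values.size:
        raise ValueError("stress indices out of background range")
    statistics = tuple(statistics)
    unknown = set(statistics) - {"mean", "chisq", "df"}
    if unknown:
        raise ValueError(f"unknown statistic(s): {sorted(unknown)}")
    want_mean = "mean" in statistics
    want_binned = bool({"chisq", "df"} & set(statistics))
    if want_binned and binning is None:
        raise ValueError("binned statistics require a binning spec")

    stress_values = values[idx]
    m = idx.size
    observed: dict = {}
    if want_mean:
        observed["mean"] = float(stress_values.mean())
    bg_freq = None
    bg_labels = ()
    if want_binned:
        bg_counts = binning.count(values)
        bg_freq = bg_counts / bg_counts.sum()
        bg_labels = tuple(binning.labels)
        obs_counts = binning.count(stress_values)
        usable = bg_freq > 0
        expected = m * bg_freq[usable]
        observed["chisq"] = float(
            ((obs_counts[usable] - expected) ** 2 / expected).sum()
        )
        observed["df"] = obs_counts / m - bg_freq

    rng = np.random.default_rng(seed)
    n_rand = {
        k: (np.zeros(len(v), dtype=int) if np.ndim(v) else 0)
        for k, v in observed.items()
    }

    # Replicates are processed in blocks: sampling-without-replacement is
    # vectorised by arg-partitioning a uniform matrix, block by block.
    block = max(1, min(n_permutations, int(4e6 // max(values.size, 1)) or 1))
    done = 0
    while done < n_permutations:
        r = min(block, n_permutations - done)
        u = rng.random((r, values.size))
        take = np.argpartition(u, m - 1, axis=1)[:, :m]
        samples = values[take]
        stats = _replicate_stats(samples, binning, bg_freq, want_mean, want_binned)
        if want_mean:
            n_rand["mean"] += int((stats["mean"] > observed["mean"]).sum())
        if "chisq" in statistics:
            n_rand["chisq"] += int((stats["chisq"] > observed["chisq"]).sum())
        if "df" in statistics:
            n_rand["df"] += (stats["df"] > observed["df"]).sum(axis=0)
        done += r

    n_rand = {k: v for k, v in n_rand.items() if k in statistics}
    observed = {k: v for k, v in observed.items() if k in statistics}
    p = {k: empirical_p(v, n_permutations) for k, v in n_rand.items()}

    def _flag(pv):
        if pv < alpha:
            return "low"
        if pv > 1.0 - alpha:
            return "high"
        return ""

    flags = {
        k: (np.array([_flag(x) for x in np.atleast_1d(v)]) if np.ndim(v) else _flag(v))
        for k, v in p.items()
    }
    return PermutationResult(
        observed=observed,
        n_rand=n_rand,
        p=p,
        flags=flags,
        n_permutations=n_permutations,
        seed=seed,
        bins=bg_labels,
        alpha=alpha,
    )


def exhaustive_permutation_test(
    background_values, stress_indices, binning=None, statistics=("mean",)
) -> dict:
    """Exact exceedance probabilities by enumerating every same-size subset.

    Feasible only for small backgrounds (C(n, m) subsets); serves as the
    ground-truth oracle the sampled test must converge to.
    """
    values = np.asarray(background_values, dtype=float)
    idx = np.asarray(stress_indices, dtype=int)
    m = idx.size
    want_mean = "mean" in statistics
    want_binned = bool({"chisq", "df"} & set(statistics))
    stress_values = values[idx]
    observed: dict = {}
    if want_mean:
        observed["mean"] = float(stress_values.mean())
    if want_binned:
        bg_counts = binning.count(values)
        bg_freq = bg_counts / bg_counts.sum()
        obs_counts = binning.count(stress_values)
        usable = bg_freq > 0
        expected = m * bg_freq[usable]
        observed["chisq"] = float(
            ((obs_counts[usable] - expected) ** 2 / expected).sum()
        )
        observed["df"] = obs_counts / m - bg_freq
    total = 0
    exceed = {
        k: (np.zeros(len(np.atleast_1d(v)), dtype=int) if np.ndim(v) else 0)
        for k, v in observed.items()
    }
    for combo in itertools.combinations(range(values.size), m):
        sample = values[list(combo)]
        total += 1
        if want_mean and sample.mean() > observed["mean"]:
            exceed["mean"] += 1
        if want_binned:
            counts = binning.count(sample)
            chisq = float(((counts[usable] - expected) ** 2 / expected).sum())
            if "chisq" in statistics and chisq > observed["chisq"]:
                exceed["chisq"] += 1
            if "df" in statistics:
                exceed["df"] += (counts / m - bg_freq) > observed["df"]
    return {
        "p": {
            k: (np.asarray(v) / total if np.ndim(v) else v / total)
            for k, v in exceed.items()
            if k in statistics
        },
        "n_subsets": total,
        "observed": {k: v for k, v in observed.items() if k in statistics},
    }


def annotated_background(all_genes, annotations):
    """Restrict a background gene list to genes with >= 1 annotation record."""
    annotated = {a.gene for a in annotations}
    return [g for g in all_genes if g in annotated]
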