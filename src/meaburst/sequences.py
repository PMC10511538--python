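"""Statistics of cluster activation sequences.

An activation sequence is the order in which clusters reach their IFR peaks
during one network burst.  On the 2x2 cluster grid a full-length sequence
from a fixed initiator can follow 6 orderings, 2 of which take only
edge-adjacent steps ("circular paths", CP); the remaining 4 cross a diagonal
("diagonal paths", DP), so random propagation yields CP with probability
1/3.  This module classifies paths, ranks initiator clusters into frequency
classes, measures sequence-type diversity with the Shannon index H and
equitability E = H/ln(N), weights runs of identical consecutive sequences,
and draws the matching Monte Carlo null samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import permutations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .layout import CLUSTERS, ClusterLayout


@dataclass(frozen=True)
class ActivationSequence:
    """Ordered recruited clusters of one network burst (length 1-4)."""

    clusters: tuple[str, ...]
    nb_index: int = -1

    def __post_init__(self) -> None:
        if not 1 <= len(self.clusters) <= 4:
            raise ValueError("sequence length must be 1-4")
        if len(set(self.clusters)) != len(self.clusters):
            raise ValueError("sequence labels must be distinct")

    @property
    def initiator(self) -> str:
        return self.clusters[0]

    def __len__(self) -> int:
        return len(self.clusters)


class PathClass(str, Enum):
    CP = "CP"  # circular: every step edge-adjacent, length >= 3
    DP = "DP"  # diagonal: >= 1 diagonal step, length >= 3
    SHORT = "SHORT"  # fewer than 3 clusters: path undefined


def classify_path(seq: ActivationSequence, layout: ClusterLayout) -> PathClass:
    """CP / DP / SHORT classification of one activation sequence."""
    if len(seq) < 3:
        return PathClass.SHORT
    for a, b in zip(seq.clusters, seq.clusters[1:]):
        if layout.is_diagonal_step(a, b):
            return PathClass.DP
    return PathClass.CP


def enumerate_paths(start_cluster: str, layout: ClusterLayout) -> tuple[int, int]:
    """Exhaustive count of full-length orderings from one initiator.

    Returns ``(n_total, n_circular)`` over all orderings of the remaining
    three clusters.
    """
    rest = [c for c in CLUSTERS if c != start_cluster]
    n_total = n_circular = 0
    for perm in permutations(rest):
        n_total += 1
        seq = ActivationSequence((start_cluster, *perm))
        if classify_path(seq, layout) is PathClass.CP:
            n_circular += 1
    return n_total, n_circular


def expected_circular(n_sequences: float) -> float:
    """Expected circular-path count under random propagation: S/3."""
    if n_sequences < 0:
        raise ValueError("sequence count must be nonnegative")
    return n_sequences / 3.0


def count_circular(
    sequences: Iterable[ActivationSequence], layout: ClusterLayout
) -> tuple[int, int]:
    """(observed CP count, number of length>=3 sequences S)."""
    n_cp = n_long = 0
    for s in sequences:
        cls = classify_path(s, layout)
        if cls is PathClass.SHORT:
            continue
        n_long += 1
        if cls is PathClass.CP:
            n_cp += 1
    return n_cp, n_long


@dataclass(frozen=True)
class InitiatorClasses:
    """Initiator relative frequencies ranked into classes 1-4."""

    class_frequencies: tuple[float, float, float, float]
    class_clusters: tuple[str, ...]
    tie: bool  # some clusters shared a frequency; ranked by label order


def initiator_classes(
    sequences: Sequence[ActivationSequence],
) -> InitiatorClasses:
    """Rank clusters by how often they initiate the experiment's sequences.

    Class 1 is the most frequent initiator, class 4 the least; ties are
    broken by fixed label order and flagged.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    counts = {c: 0 for c in CLUSTERS}
    for s in sequences:
        counts[s.initiator] += 1
    total = len(sequences)
    ranked = sorted(CLUSTERS, key=lambda c: (-counts[c], c))
    freqs = tuple(counts[c] / total for c in ranked)
    tie = len(set(counts.values())) < 4
    return InitiatorClasses(freqs, tuple(ranked), tie)


def pooled_class_medians(
    per_experiment: Sequence[InitiatorClasses],
) -> tuple[float, float, float, float]:
    """Median relative frequency of each initiator class across experiments."""
    arr = np.array([ic.class_frequencies for ic in per_experiment])
    return tuple(float(x) for x in np.median(arr, axis=0))


def shannon(p: Sequence[float]) -> float:
    """Shannon diversity H = -sum p_i ln p_i (0*ln0 := 0), in nats."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability vector")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def equitability(h: float, n_types: int) -> float:
    """Shannon equitability E = H/ln(N) in [0, 1]; E := 0 for a single type."""
    if n_types < 1:
        raise ValueError("need at least one type")
    if n_types == 1:
        return 0.0
    return h / np.log(n_types)


@dataclass(frozen=True)
class DiversityResult:
    h: float  # nats
    e: float  # in [0, 1]
    n_types: int
    frequencies: tuple[float, ...]


def sequence_diversity(sequences: Sequence[ActivationSequence]) -> DiversityResult:
    """Shannon diversity / equitability of the sequence-type distribution."""
    if not sequences:
        raise ValueError("need at least one sequence")
    counts: dict[tuple[str, ...], int] = {}
    for s in sequences:
        counts[s.clusters] = counts.get(s.clusters, 0) + 1
    p = np.array(sorted(counts.values(), reverse=True), dtype=float)
    p /= p.sum()
    h = shannon(p)
    return DiversityResult(h, equitability(h, p.size), p.size, tuple(p))


def monte_carlo_sequences(
    lengths: Sequence[int],
    seed: int,
    rng: np.random.Generator | None = None,
) -> list[ActivationSequence]:
    """Random activation sequences matching an observed length multiset.

    For each requested length k, a sequence is drawn uniformly over all
    ordered selections of k distinct clusters (the null of fully random
    propagation with every cluster equally likely to initiate).
    """
    if len(lengths) < 1:
        raise ValueError("need at least one sequence length")
    if any(not 1 <= k <= 4 for k in lengths):
        raise ValueError("lengths must lie in 1..4")
    if rng is None:
        rng = np.random.default_rng(seed)
    out = []
    labels = np.array(CLUSTERS)
    for i, k in enumerate(lengths):
        perm = rng.permutation(4)[:k]
        out.append(ActivationSequence(tuple(labels[perm]), nb_index=i))
    return out


@dataclass
class SeriesTable:
    """Weighted occurrence of runs of identical consecutive sequences.

    One row per series length L >= 2: the number of maximal runs of exactly
    L identical consecutive sequences (occurrences O_L), their weighted
    absolute frequency W = L * O_L, the relative frequencies of W and their
    cumulative distribution over ascending L.
    """

    table: pd.DataFrame  # index L, columns: occurrences, weight, rel_freq, cum_freq

    @property
    def empty(self) -> bool:
        return self.table.empty

    def weight(self, length: int) -> float:
        """Weighted absolute frequency W = L * O_L for series length L."""
        if length not in self.table.index:
            return 0.0
        return float(self.table.loc[length, "weight"])


def find_series(sequences: Sequence[ActivationSequence]) -> SeriesTable:
    """Maximal runs of identical consecutive sequences, weighted by length.

    Sequences are compared as full orderings (same clusters, same order,
    same length).  Runs of length 1 are not series and are excluded.
    """
    run_lengths: list[int] = []
    i = 0
    seqs = [s.clusters for s in sequences]
    while i < len(seqs):
        j = i
        while j + 1 < len(seqs) and seqs[j + 1] == seqs[i]:
            j += 1
        if j > i:
            run_lengths.append(j - i + 1)
        i = j + 1
    if not run_lengths:
        return SeriesTable(
            pd.DataFrame(columns=["occurrences", "weight", "rel_freq", "cum_freq"])
        )
    lengths, counts = np.unique(run_lengths, return_counts=True)
    weight = lengths * counts
    rel = weight / weight.sum()
    df = pd.DataFrame(
        {
            "occurrences": counts,
            "weight": weight,
            "rel_freq": rel,
            "cum_freq": np.cumsum(rel),
        },
        index=pd.Index(lengths, name="series_length"),
    )
    return SeriesTable(df)


_TESTS = {
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "kruskal_wallis",
    "chi_squared",
    "kolmogorov_smirnov",
}

ALPHA = 0.05


def compare(
    *samples: Sequence[float],
    test: str,
    expected: Sequence[float] | None = None,
    n_comparisons: int = 1,
) -> tuple[float, float]:
    """Nonparametric test battery; returns (statistic, two-sided p).

    ``wilcoxon_signed_rank`` pairs the two samples; ``mann_whitney_u``
    compares two independent samples (p multiplied by ``n_comparisons`` for
    Bonferroni-corrected post-hocs); ``kruskal_wallis`` takes >= 2 samples;
    ``chi_squared`` tests observed counts against ``expected`` (uniform when
    omitted); ``kolmogorov_smirnov`` compares two empirical distributions.
    """
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    if test == "wilcoxon_signed_rank":
        a, b = (np.asarray(s, dtype=float) for s in samples)
        if a.shape != b.shape:
            raise ValueError("paired samples must have equal length")
        if np.allclose(a, b):
            return 0.0, 1.0  # no effect: identical pairs
        res = stats.wilcoxon(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney_u":
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        return float(res.statistic), float(min(1.0, res.pvalue * n_comparisons))
    if test == "kruskal_wallis":
        res = stats.kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    if test == "chi_squared":
        observed = np.asarray(samples[0], dtype=float)
        res = stats.chisquare(observed, f_exp=expected)
        return float(res.statistic), float(res.pvalue)
    res = stats.ks_2samp(samples[0], samples[1])
    return float(res.statistic), float(res.pvalue)
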