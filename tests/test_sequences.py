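"""Path classification, initiator hierarchy, diversity, repeated series."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import meaburst as mb
from meaburst import sequences as sq
from meaburst.sequences import ActivationSequence, PathClass


def seq(*labels):
    return ActivationSequence(tuple(labels))


# ---------------------------------------------------------------- paths


def test_classify_path_examples(layout):
    assert sq.classify_path(seq("A", "B", "C", "D"), layout) is PathClass.CP
    assert sq.classify_path(seq("A", "C", "B"), layout) is PathClass.DP
    assert sq.classify_path(seq("A", "B"), layout) is PathClass.SHORT
    assert sq.classify_path(seq("A"), layout) is PathClass.SHORT
    # diagonal step at the end
    assert sq.classify_path(seq("A", "B", "D"), layout) is PathClass.DP
    # 3-cluster walk along edges only
    assert sq.classify_path(seq("A", "B", "C"), layout) is PathClass.CP


def test_enumerate_paths_counts(layout):
    for start in "ABCD":
        n_total, n_circular = sq.enumerate_paths(start, layout)
        assert n_total == 6
        assert n_circular == 2
        assert n_circular / n_total == pytest.approx(1 / 3)


def test_enumerate_paths_matches_brute_force(layout):
    """Oracle identity: recount by raw permutation enumeration."""
    diagonal = {frozenset({"A", "C"}), frozenset({"B", "D"})}
    for start in "ABCD":
        rest = [c for c in "ABCD" if c != start]
        brute_total = brute_cp = 0
        for perm in permutations(rest):
            brute_total += 1
            path = (start, *perm)
            if all(frozenset(p) not in diagonal for p in zip(path, path[1:])):
                brute_cp += 1
        assert sq.enumerate_paths(start, layout) == (brute_total, brute_cp)


@pytest.mark.parametrize("s,expected", [(0, 0.0), (300, 100.0), (10, 10 / 3)])
def test_expected_circular(s, expected):
    assert sq.expected_circular(s) == pytest.approx(expected)


# ---------------------------------------------------------------- initiators


def test_initiator_classes_ranked_frequencies():
    seqs = (
        [seq("A", "B") for _ in range(50)]
        + [seq("B", "A") for _ in range(30)]
        + [seq("C", "D") for _ in range(15)]
        + [seq("D", "C") for _ in range(5)]
    )
    ic = sq.initiator_classes(seqs)
    assert ic.class_frequencies == pytest.approx((0.5, 0.3, 0.15, 0.05))
    assert ic.class_clusters == ("A", "B", "C", "D")
    assert not ic.tie


def test_initiator_tie_flagged_label_order():
    seqs = [seq("B", "A"), seq("A", "B")]
    ic = sq.initiator_classes(seqs)
    assert ic.tie
    assert ic.class_clusters[0] == "A"  # ties broken by fixed label order


def test_uniform_null_class_medians_near_quarter():
    """Under the uniform null each class median tends to 0.25 as n grows."""
    rng = np.random.default_rng(0)
    experiments = []
    for _ in range(40):
        draws = sq.monte_carlo_sequences([4] * 2000, seed=int(rng.integers(2**31)))
        experiments.append(sq.initiator_classes(draws))
    medians = sq.pooled_class_medians(experiments)
    assert all(abs(m - 0.25) < 0.05 for m in medians)


# ---------------------------------------------------------------- diversity


def test_shannon_closed_forms():
    assert sq.shannon([1.0]) == 0.0
    assert sq.shannon([0.5, 0.5]) == pytest.approx(np.log(2))
    n = 7
    assert sq.shannon([1 / n] * n) == pytest.approx(np.log(n))
    assert sq.shannon([0.5, 0.5, 0.0]) == pytest.approx(np.log(2))  # 0 ln 0 = 0


def test_equitability_bounds():
    assert sq.equitability(0.0, 1) == 0.0
    assert sq.equitability(np.log(5), 5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        sq.equitability(0.0, 0)


def test_sequence_diversity_single_type_is_zero():
    d = sq.sequence_diversity([seq("A", "B", "C", "D")] * 9)
    assert d.h == 0.0 and d.e == 0.0 and d.n_types == 1


# ---------------------------------------------------------------- Monte Carlo


def test_monte_carlo_reproducible_and_length_matched():
    lengths = [4, 3, 2, 1, 4, 4]
    a = sq.monte_carlo_sequences(lengths, seed=3)
    b = sq.monte_carlo_sequences(lengths, seed=3)
    assert [s.clusters for s in a] == [s.clusters for s in b]
    assert [len(s) for s in a] == lengths


def test_monte_carlo_cp_fraction_one_third(layout):
    draws = sq.monte_carlo_sequences([4] * 10_000, seed=7)
    n_cp, n_long = sq.count_circular(draws, layout)
    se = np.sqrt((1 / 3) * (2 / 3) / n_long)
    assert abs(n_cp / n_long - 1 / 3) <= 3 * se


def test_monte_carlo_initiators_uniform():
    draws = sq.monte_carlo_sequences([4] * 10_000, seed=11)
    counts = {c: 0 for c in "ABCD"}
    for s in draws:
        counts[s.initiator] += 1
    for c in "ABCD":
        p = counts[c] / 10_000
        se = np.sqrt(0.25 * 0.75 / 10_000)
        assert abs(p - 0.25) <= 3 * se
    _, p = sq.compare([counts[c] for c in "ABCD"], test="chi_squared")
    assert p > 0.001


# ---------------------------------------------------------------- series


def test_series_worked_weights():
    """A length-2 series occurring 10 times and a length-4 series occurring
    5 times both carry weighted absolute frequency 20."""
    a, b, filler = seq("A", "B", "C", "D"), seq("B", "A", "D", "C"), seq("C", "D")
    chronological = []
    for _ in range(10):
        chronological += [a, a, filler]
    table2 = sq.find_series(chronological)
    assert table2.table.loc[2, "occurrences"] == 10
    assert table2.weight(2) == 20.0

    chronological = []
    for _ in range(5):
        chronological += [b, b, b, b, filler]
    table4 = sq.find_series(chronological)
    assert table4.table.loc[4, "occurrences"] == 5
    assert table4.weight(4) == 20.0


def test_series_all_distinct_is_empty():
    seqs = [seq("A", "B"), seq("B", "A"), seq("C", "D"), seq("D", "C")]
    assert sq.find_series(seqs).empty


def test_series_identity_requires_order_and_length():
    """(A,B,C) != (A,C,B) and != (A,B,C,D): no run across different types."""
    seqs = [seq("A", "B", "C"), seq("A", "C", "B"), seq("A", "B", "C", "D")]
    assert sq.find_series(seqs).empty


def test_series_cumulative_distribution_properties():
    a, b = seq("A", "B"), seq("B", "A")
    seqs = [a, a, b, a, a, a, b, b]
    table = sq.find_series(seqs).table
    assert (table["weight"] == table.index * table["occurrences"]).all()
    assert np.all(np.diff(table["cum_freq"]) >= 0)
    assert table["cum_freq"].iloc[-1] == pytest.approx(1.0)


@settings(max_examples=200, deadline=None)
@given(
    codes=st.lists(st.integers(min_value=0, max_value=3), min_size=0, max_size=200)
)
def test_series_match_brute_force_scan(codes):
    """Oracle equivalence with a direct run-length scan (n <= 200)."""
    types = [seq("A"), seq("B"), seq("C"), seq("D")]
    seqs = [types[c] for c in codes]
    got = sq.find_series(seqs)
    # brute force: walk the list, count maximal runs
    runs = {}
    i = 0
    while i < len(codes):
        j = i
        while j + 1 < len(codes) and codes[j + 1] == codes[i]:
            j += 1
        if j > i:
            runs[j - i + 1] = runs.get(j - i + 1, 0) + 1
        i = j + 1
    expected = {length: length * occ for length, occ in runs.items()}
    assert {int(k): float(got.weight(k)) for k in got.table.index} == expected


# ---------------------------------------------------------------- tests API


def test_compare_identical_paired_samples():
    stat, p = sq.compare([1, 2, 3], [1, 2, 3], test="wilcoxon_signed_rank")
    assert p == 1.0


def test_compare_uniform_chi_squared_zero():
    stat, p = sq.compare([25, 25, 25, 25], test="chi_squared")
    assert stat == 0.0 and p == 1.0


def test_compare_rejects_unknown_test():
    with pytest.raises(ValueError):
        sq.compare([1], [2], test="t_test")


def test_dominant_sequences_depress_equitability(layout):
    """Observed E < Expected E (Wilcoxon p < 0.05) for a generator with a
    dominant, repetitive sequence type — the direction real modular cultures
    show."""
    obs_e, exp_e = [], []
    for k in range(12):
        params = mb.SimulationParams(
            seed=300 + k, duration=60.0, repeat_run_prob=0.5,
            initiator_probs=(0.7, 0.2, 0.05, 0.05), circular_bias=0.9,
        )
        _, truth = mb.simulate_recording(params, layout)
        seqs = [ActivationSequence(t.sequence) for t in truth]
        null = sq.monte_carlo_sequences([len(s) for s in seqs], seed=400 + k)
        obs_e.append(sq.sequence_diversity(seqs).e)
        exp_e.append(sq.sequence_diversity(null).e)
    assert np.median(obs_e) < np.median(exp_e)
    _, p = sq.compare(obs_e, exp_e, test="wilcoxon_signed_rank")
    assert p < 0.05


def test_circular_bias_detected_only_when_present(layout):
    """Observed CP > S/3 (Wilcoxon p < 0.05) for adjacency-biased
    propagation; no significant excess for unbiased propagation."""
    def experiment_counts(bias, seed0):
        obs, exp = [], []
        for k in range(16):
            params = mb.SimulationParams(
                seed=seed0 + k, duration=60.0, circular_bias=bias
            )
            _, truth = mb.simulate_recording(params, layout)
            seqs = [ActivationSequence(t.sequence) for t in truth]
            n_cp, n_long = sq.count_circular(seqs, layout)
            obs.append(n_cp)
            exp.append(sq.expected_circular(n_long))
        return obs, exp

    obs, exp = experiment_counts(bias=0.75, seed0=100)
    _, p_biased = sq.compare(obs, exp, test="wilcoxon_signed_rank")
    assert np.median(np.array(obs) - np.array(exp)) > 0
    assert p_biased < 0.05

    obs, exp = experiment_counts(bias=0.0, seed0=200)
    _, p_unbiased = sq.compare(obs, exp, test="wilcoxon_signed_rank")
    assert p_unbiased > 0.05
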