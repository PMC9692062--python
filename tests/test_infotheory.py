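"""Entropy ladders, I_t profiles, tradeoff curves, and the exact oracle."""

from __future__ import annotations

import itertools
import math
import random
from collections import defaultdict

import pytest
from hypothesis import given
from hypothesis import strategies as st

from morphtrade import (
    StringDistribution,
    auc,
    estimate_entropy_ladder,
    exact_it,
    it_profile,
    tradeoff_curve,
)


def brute_force_positional_mi(dist, k):
    """Independent oracle: I(S_k ; S_1..S_{k-1}) decomposed stepwise is not
    needed — here, the mutual information between position k and position
    k-1 .. specifically I(S_k ; S_{k-1} | nothing) for length-2 strings,
    via direct enumeration of the joint table."""
    joint = defaultdict(float)
    for s, p in dist:
        joint[(s[k - 2], s[k - 1])] += p
    px = defaultdict(float)
    py = defaultdict(float)
    for (x, y), p in joint.items():
        px[x] += p
        py[y] += p
    return sum(
        p * math.log2(p / (px[x] * py[y])) for (x, y), p in joint.items() if p > 0
    )


class TestExactOracle:
    def test_copy_distribution_carries_one_bit(self):
        d = StringDistribution(((("A", "A"), 0.5), (("B", "B"), 0.5)))
        prof = exact_it(d, 2)
        assert prof.it_values[0] == pytest.approx(1.0, abs=1e-12)
        assert prof.it_values[1] == pytest.approx(0.0, abs=1e-12)

    def test_skewed_two_symbol_distribution(self):
        items = ((("A", "A"), 0.5), (("A", "B"), 0.25), (("B", "A"), 0.25))
        d = StringDistribution(items)
        prof = exact_it(d, 2)
        oracle = brute_force_positional_mi(items, 2)
        assert oracle == pytest.approx(0.1225562489, abs=1e-9)
        assert prof.it_values[0] == pytest.approx(oracle, abs=1e-12)

    def test_product_distribution_has_zero_information(self):
        px = {"A": 0.6, "B": 0.4}
        py = {"A": 0.3, "B": 0.7}
        d = StringDistribution(
            tuple(((x, y), px[x] * py[y]) for x in px for y in py)
        )
        prof = exact_it(d, 2)
        assert prof.it_values == pytest.approx((0.0, 0.0), abs=1e-12)

    def test_table_size_cap(self):
        d = StringDistribution(((("A", "A"), 0.5), (("B", "B"), 0.5)))
        with pytest.raises(ValueError, match="cap"):
            exact_it(d, 2, max_positions=3)

    def test_relabeling_invariance(self):
        items = ((("A", "A"), 0.5), (("A", "B"), 0.25), (("B", "A"), 0.25))
        relabeled = tuple(
            (tuple({"A": "Q", "B": "R"}[s] for s in seq), p) for seq, p in items
        )
        a = exact_it(StringDistribution(items), 2)
        b = exact_it(StringDistribution(relabeled), 2)
        assert a.entropy_ladder == b.entropy_ladder


class TestPluginEstimator:
    def test_matches_exact_on_exact_multiplicities(self):
        seqs = [("A", "A")] * 2 + [("A", "B")] + [("B", "A")]
        d = StringDistribution(
            ((("A", "A"), 0.5), (("A", "B"), 0.25), (("B", "A"), 0.25))
        )
        ladder = estimate_entropy_ladder(seqs, 2)
        assert ladder == pytest.approx(exact_it(d, 2).entropy_ladder, abs=1e-12)

    def test_weights_equal_replication(self):
        seqs = [("A", "A"), ("A", "B"), ("B", "A")]
        weighted = estimate_entropy_ladder(seqs, 2, weights=[2, 1, 1])
        replicated = estimate_entropy_ladder(
            [("A", "A")] * 2 + [("A", "B")] + [("B", "A")], 2
        )
        assert weighted == pytest.approx(replicated, abs=1e-12)

    def test_iid_single_symbol_words_have_flat_ladder(self):
        seqs = [("A",)] * 50 + [("B",)] * 50
        ladder = estimate_entropy_ladder(seqs, 1)
        assert ladder[0] == pytest.approx(1.0, abs=1e-12)
        assert ladder[1] == pytest.approx(ladder[0], abs=1e-12)

    @given(
        st.lists(
            st.lists(st.sampled_from("ABC"), min_size=1, max_size=4).map(tuple),
            min_size=1,
            max_size=12,
        )
    )
    def test_ladder_is_nonincreasing(self, seqs):
        ladder = estimate_entropy_ladder(seqs, 4)
        for a, b in zip(ladder, ladder[1:]):
            assert b <= a + 1e-12

    def test_errors(self):
        with pytest.raises(ValueError, match="t_max"):
            estimate_entropy_ladder([("A",)], 0)
        with pytest.raises(ValueError):
            estimate_entropy_ladder([], 2)
        with pytest.raises(ValueError, match="k_folds"):
            estimate_entropy_ladder([("A",)] * 3, 1, "heldout", k_folds=10)

    def test_heldout_is_finite_and_tracks_plugin(self):
        rng = random.Random(0)
        seqs = [
            tuple(rng.choice("AB") for _ in range(rng.randint(1, 3)))
            for _ in range(200)
        ]
        held = estimate_entropy_ladder(seqs, 3, "heldout", k_folds=5, seed=1)
        plug = estimate_entropy_ladder(seqs, 3)
        assert all(math.isfinite(h) for h in held)
        # held-out cross-entropy upper-bounds the plug-in estimate
        assert all(h >= p - 1e-9 for h, p in zip(held, plug))


class TestProfileAndCurve:
    def test_profile_is_ladder_difference(self):
        prof = it_profile([2.0, 1.0, 1.0])
        assert prof.it_values == (1.0, 0.0)
        assert prof.n_clipped == 0

    def test_constant_ladder_gives_zero_profile(self):
        assert it_profile([1.5, 1.5, 1.5]).it_values == (0.0, 0.0)

    def test_negative_differences_clip_and_count(self):
        prof = it_profile([1.0, 0.8, 0.9])
        assert prof.it_values == (pytest.approx(0.2), 0.0)
        assert prof.n_clipped == 1

    def test_single_term_curve(self):
        curve = tradeoff_curve(it_profile([2.0, 1.0]))
        assert [(p.T, p.memory_bits, p.excess_surprisal_bits) for p in curve.points] == [
            (0, 0.0, 1.0),
            (1, 1.0, 0.0),
        ]
        assert curve.s_inf_estimate == 1.0

    def test_two_term_curve_hand_evaluated(self):
        curve = tradeoff_curve(it_profile([2.5, 1.5, 1.0]))
        pts = [(p.T, p.memory_bits, p.excess_surprisal_bits) for p in curve.points]
        assert pts == [(0, 0.0, 1.5), (1, 1.0, 0.5), (2, 2.0, 0.0)]

    def test_zero_profile_curve_and_auc(self):
        curve = tradeoff_curve(it_profile([1.0, 1.0, 1.0]))
        assert all(p.memory_bits == 0.0 for p in curve.points)
        assert auc(curve) == 0.0

    @pytest.mark.parametrize(
        "ladder, expected",
        [([2.0, 1.0], 0.5), ([2.5, 1.5, 1.0], 1.25)],
    )
    def test_auc_hand_checked(self, ladder, expected):
        assert auc(tradeoff_curve(it_profile(ladder))) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.0, 3.0), min_size=1, max_size=6),
        st.floats(0.1, 2.0),
    )
    def test_slope_law_and_monotonicity(self, it_values, s_inf):
        ladder = [s_inf + math.fsum(it_values)]
        for i in it_values:
            ladder.append(ladder[-1] - i)
        curve = tradeoff_curve(it_profile(ladder))
        for a, b in zip(curve.points, curve.points[1:]):
            assert b.memory_bits >= a.memory_bits - 1e-12
            assert b.excess_surprisal_bits <= a.excess_surprisal_bits + 1e-12
            if it_values[b.T - 1] > 1e-3:
                slope = (b.excess_surprisal_bits - a.excess_surprisal_bits) / (
                    b.memory_bits - a.memory_bits
                )
                assert slope == pytest.approx(-1.0 / b.T, abs=1e-9)
        assert curve.points[-1].excess_surprisal_bits == 0.0


class TestStringDistribution:
    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError, match="sum"):
            StringDistribution(((("A",), 0.5), (("B",), 0.6)))
        with pytest.raises(ValueError, match="positive"):
            StringDistribution(((("A",), 1.2), (("B",), -0.2)))
        with pytest.raises(ValueError, match="duplicate"):
            StringDistribution(((("A",), 0.5), (("A",), 0.5)))

    def test_reversal_helper(self):
        d = StringDistribution(((("A", "B"), 1.0),))
        assert d.reversed().items == ((("B", "A"), 1.0),)


def test_conservation_without_clipping():
    rng = random.Random(3)
    seqs = [
        tuple(rng.choice("ABCD") for _ in range(rng.randint(1, 4)))
        for _ in range(100)
    ]
    ladder = estimate_entropy_ladder(seqs, 5)
    prof = it_profile(ladder)
    assert prof.n_clipped == 0
    assert math.fsum(prof.it_values) == pytest.approx(
        ladder[0] - ladder[-1], abs=1e-12
    )


def test_markov_source_has_no_information_beyond_distance_one():
    rng = random.Random(5)
    alphabet = "AB"
    init = [0.3, 0.7]
    trans = {"A": {"A": 0.9, "B": 0.1}, "B": {"A": 0.4, "B": 0.6}}
    items = []
    for s in itertools.product(alphabet, repeat=4):
        p = init[alphabet.index(s[0])]
        for x, y in zip(s, s[1:]):
            p *= trans[x][y]
        items.append((s, p))
    d = StringDistribution(tuple(items))
    prof = exact_it(d, 5)
    assert max(prof.it_values[1:]) <= 1e-12
    rev = exact_it(d.reversed(), 5)
    assert prof.it_values == pytest.approx(rev.it_values, abs=1e-12)
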