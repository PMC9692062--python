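"""Pairwise ordering accuracy, baseline quantiles, and root-affix CMI."""

from __future__ import annotations

import itertools
import math
import random

import pytest

from morphtrade import (
    Affix,
    Corpus,
    MorphWord,
    OrderingGrammar,
    SlotSchema,
    SlotSpec,
    baseline_quantile,
    cmi_table,
    pairwise_accuracy,
    real_grammar,
    reverse_grammar,
    root_affix_cmi,
    sample_random_grammar,
)

from .conftest import suffix


def brute_force_accuracy(corpus, candidate, reference) -> float:
    agree = total = 0
    for w in corpus.words:
        for side_affixes in (w.prefixes, w.suffixes):
            for a, b in itertools.combinations(side_affixes, 2):
                total += 1
                if (candidate.ranks[a.slot_id] - candidate.ranks[b.slot_id]) * (
                    reference.ranks[a.slot_id] - reference.ranks[b.slot_id]
                ) > 0:
                    agree += 1
    return agree / total


class TestPairwiseAccuracy:
    @pytest.fixture
    def ncp_corpus(self, noun_schema):
        def word(*slots):
            return MorphWord(
                "r", suffixes=tuple(suffix(s, s.lower()) for s in slots)
            )

        return Corpus(
            (
                word("Number", "Case"),
                word("Number", "Poss"),
                word("Number", "Case", "Poss"),
            ),
            noun_schema,
        )

    def test_identical_grammars_score_one(self, ncp_corpus, noun_schema):
        real = real_grammar(noun_schema)
        assert pairwise_accuracy(ncp_corpus, real, real) == 1.0

    def test_hand_enumerated_partial_agreement(self, ncp_corpus):
        # reference N<C<P, candidate N<P<C: the single C-P pair disagrees;
        # 4 of the 5 attested pairs agree
        reference = OrderingGrammar({"Number": 1, "Case": 2, "Poss": 3})
        candidate = OrderingGrammar({"Number": 1, "Poss": 2, "Case": 3})
        assert pairwise_accuracy(ncp_corpus, candidate, reference) == pytest.approx(
            0.8
        )

    def test_reverse_complement_law(self, ncp_corpus, noun_schema):
        real = real_grammar(noun_schema)
        rev = reverse_grammar(real, noun_schema)
        assert pairwise_accuracy(ncp_corpus, rev, real) == pytest.approx(0.0)

    def test_no_evaluable_pairs_is_an_error(self, noun_schema):
        corpus = Corpus(
            (MorphWord("r", suffixes=(suffix("Number", "pl"),)),), noun_schema
        )
        g = real_grammar(noun_schema)
        with pytest.raises(ValueError, match="accuracy undefined"):
            pairwise_accuracy(corpus, g, g)

    def test_matches_brute_force_on_random_corpora(self, noun_schema):
        rng = random.Random(0)
        real = real_grammar(noun_schema)
        for trial in range(20):
            words = []
            for _ in range(rng.randint(1, 15)):
                slots = [
                    s
                    for s in ("Number", "Case", "Poss")
                    if rng.random() < 0.7
                ]
                words.append(
                    MorphWord(
                        f"r{rng.randint(1, 3)}",
                        suffixes=tuple(suffix(s, s.lower()) for s in slots),
                    )
                )
            corpus = Corpus(tuple(words), noun_schema)
            candidate = sample_random_grammar(noun_schema, trial)
            try:
                fast = pairwise_accuracy(corpus, candidate, real)
            except ValueError:
                continue
            assert fast == pytest.approx(
                brute_force_accuracy(corpus, candidate, real), abs=1e-15
            )

    def test_invariant_to_word_order_and_duplication(self, ncp_corpus):
        reference = OrderingGrammar({"Number": 1, "Case": 2, "Poss": 3})
        candidate = OrderingGrammar({"Number": 1, "Poss": 2, "Case": 3})
        base = pairwise_accuracy(ncp_corpus, candidate, reference)
        shuffled = Corpus(tuple(reversed(ncp_corpus.words)), ncp_corpus.schema)
        doubled = Corpus(ncp_corpus.words * 2, ncp_corpus.schema)
        assert pairwise_accuracy(shuffled, candidate, reference) == base
        assert pairwise_accuracy(doubled, candidate, reference) == base


class TestBaselineQuantile:
    def test_better_than_all(self):
        assert baseline_quantile(1.0, [2, 3, 4], better="lower") == 1.0
        assert baseline_quantile(5.0, [2, 3, 4], better="higher") == 1.0

    def test_ties_are_not_worse(self):
        assert baseline_quantile(3.0, [3.0, 3.0, 3.0], better="lower") == 0.0

    def test_direct_count(self):
        assert baseline_quantile(5, [1, 4, 6, 9], better="lower") == 0.5
        assert baseline_quantile(5, [1, 4, 6, 9], better="higher") == 0.5

    def test_empty_baselines_rejected(self):
        with pytest.raises(ValueError):
            baseline_quantile(1.0, [], better="lower")
        with pytest.raises(ValueError, match="better"):
            baseline_quantile(1.0, [1.0], better="sideways")


def two_slot_schema() -> SlotSchema:
    return SlotSchema((SlotSpec("V", "suffix", 1, "voice"),))


class TestRootAffixCmi:
    def test_independent_value_gives_zero(self):
        # product construction with exact multiplicities
        schema = two_slot_schema()
        words = []
        for root, rn in (("r1", 2), ("r2", 2)):
            for value, vn in (("a", 3), ("b", 1)):
                words += [
                    MorphWord(root, suffixes=(Affix("V", value, "suffix"),))
                ] * (rn * vn)
        corpus = Corpus(tuple(words), schema)
        assert root_affix_cmi(corpus, real_grammar(schema), "V") == pytest.approx(
            0.0, abs=1e-12
        )

    def test_deterministic_coupling_gives_one_bit(self):
        schema = two_slot_schema()
        words = tuple(
            MorphWord(root, suffixes=(Affix("V", value, "suffix"),))
            for root, value in (("r1", "a"), ("r2", "b"))
            for _ in range(5)
        )
        corpus = Corpus(words, schema)
        assert root_affix_cmi(corpus, real_grammar(schema), "V") == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_brute_force_on_explicit_table(self):
        # 3 roots x 2 values with a planted, non-uniform joint table
        schema = two_slot_schema()
        table = {
            ("r1", "a"): 6,
            ("r1", "b"): 2,
            ("r2", "a"): 1,
            ("r2", "b"): 3,
            ("r3", "a"): 2,
            ("r3", "b"): 2,
        }
        words = tuple(
            MorphWord(r, suffixes=(Affix("V", v, "suffix"),))
            for (r, v), n in sorted(table.items())
            for _ in range(n)
        )
        corpus = Corpus(words, schema)
        # brute force: average pointwise log2[P(v|r)/P(v)] over tokens
        n = sum(table.values())
        pr = {r: sum(c for (rr, _), c in table.items() if rr == r) for r in "r1 r2 r3".split()}
        pv = {v: sum(c for (_, vv), c in table.items() if vv == v) for v in "ab"}
        oracle = (
            sum(
                c * math.log2((c / pr[r]) / (pv[v] / n))
                for (r, v), c in table.items()
            )
            / n
        )
        got = root_affix_cmi(corpus, real_grammar(schema), "V")
        assert got == pytest.approx(oracle, abs=1e-12)

    def test_unattested_target_rejected(self, noun_schema, juttu_corpus):
        with pytest.raises(ValueError, match="unattested|neither"):
            root_affix_cmi(juttu_corpus, real_grammar(noun_schema), "derivation")

    def test_class_target_pools_its_slots(self, noun_schema, juttu_corpus):
        g = real_grammar(noun_schema)
        by_id = root_affix_cmi(juttu_corpus, g, "Number")
        by_class = root_affix_cmi(juttu_corpus, g, "number")
        assert by_id == by_class  # exactly one slot in the class

    def test_crossfit_recovers_strong_coupling(self):
        schema = two_slot_schema()
        rng = random.Random(0)
        words = tuple(
            MorphWord(
                f"r{i % 2}",
                suffixes=(
                    Affix("V", "a" if i % 2 else "b", "suffix"),
                ),
            )
            for i in range(400)
        )
        corpus = Corpus(words, schema)
        v = root_affix_cmi(
            corpus, real_grammar(schema), "V", estimator="crossfit", seed=1
        )
        assert 0.8 < v < 1.1

    def test_cmi_table_covers_slots_and_classes(self, noun_schema, juttu_corpus):
        by_slot, by_class = cmi_table(juttu_corpus, real_grammar(noun_schema))
        assert set(by_slot) == {"Number", "Case", "Poss"}
        assert set(by_class) == {"number", "case", "possessive"}
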