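"""Shared fixtures: schemas, toy corpora, and generated fixture corpora."""

from __future__ import annotations

import pytest
from hypothesis import settings

from morphtrade import (
    Affix,
    Corpus,
    MorphWord,
    SlotSchema,
    SlotSpec,
    SynthConfig,
    SynthSlot,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def noun_schema() -> SlotSchema:
    """Finnish-style noun suffixes: Number, Case, Possessive (root-outward)."""
    return SlotSchema(
        (
            SlotSpec("Number", "suffix", 1, "number"),
            SlotSpec("Case", "suffix", 2, "case"),
            SlotSpec("Poss", "suffix", 3, "possessive"),
        )
    )


@pytest.fixture
def mixed_schema() -> SlotSchema:
    """A schema with affixes on both sides (Sesotho-style verb template)."""
    return SlotSchema(
        (
            SlotSpec("Agr", "prefix", 1, "agreement"),
            SlotSpec("Neg", "prefix", 2, "other"),
            SlotSpec("Voice", "suffix", 1, "voice"),
            SlotSpec("TAM", "suffix", 2, "TAM"),
        )
    )


def suffix(slot: str, value: str) -> Affix:
    return Affix(slot, value, "suffix")


def prefix(slot: str, value: str) -> Affix:
    return Affix(slot, value, "prefix")


@pytest.fixture
def juttu_word() -> MorphWord:
    """'juttu-Plural-Illative-2sgPoss' (Finnish: 'into your stories')."""
    return MorphWord(
        "juttu",
        suffixes=(
            suffix("Number", "Plural"),
            suffix("Case", "Illative"),
            suffix("Poss", "2sgPoss"),
        ),
    )


@pytest.fixture
def juttu_corpus(noun_schema, juttu_word) -> Corpus:
    talo = MorphWord(
        "talo", suffixes=(suffix("Number", "Plural"), suffix("Case", "Inessive"))
    )
    bare = MorphWord("kissa")
    return Corpus((juttu_word, talo, bare), noun_schema)


def small_synth_config(
    seed: int, n_slots: int = 3, n_tokens: int = 300
) -> SynthConfig:
    """A compact synthetic language for search-oracle fixtures."""
    lam = [0.9, 0.6, 0.3, 0.1][:n_slots]
    dep = [0.4, 0.2, 0.1, 0.0][:n_slots]
    base = [0.9, 0.8, 0.7, 0.6][:n_slots]
    slots = tuple(
        SynthSlot(f"S{i + 1}", "suffix", 3, base[i], dep[i], lam[i])
        for i in range(n_slots)
    )
    return SynthConfig(
        n_roots=12,
        zipf_s=1.0,
        n_classes=2,
        slots=slots,
        planted_real_order={"suffix": tuple(f"S{i + 1}" for i in range(n_slots))},
        n_tokens=n_tokens,
        seed=seed,
    )
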