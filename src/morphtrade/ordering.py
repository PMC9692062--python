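"""Slot schemas, ordering grammars, and word linearization.

Words in agglutinative languages are modelled as a root plus a set of
templatic affix slots (e.g. Number, Case, Possessive on Finnish nouns).
A :class:`SlotSchema` declares the slots, which side of the root each
attaches to, its typological class, and its attested rank (distance from
the root, rank 1 = adjacent).  An :class:`OrderingGrammar` is one total
order per side over those slots; applying a grammar to a word produces a
left-to-right symbol string, the *linearization*.  Counterfactual grammars
reorder the abstract morpheme labels only — no morphophonology is
attempted, and a slot never changes side.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .corpus_io import Corpus, MorphWord

__all__ = [
    "PREFIX",
    "SUFFIX",
    "UNIVERSAL_CLASSES",
    "SlotSpec",
    "SlotSchema",
    "OrderingGrammar",
    "SymbolSequence",
    "real_grammar",
    "reverse_grammar",
    "linearize",
    "apply_grammar",
]

PREFIX = "prefix"
SUFFIX = "suffix"
_SIDES = (PREFIX, SUFFIX)

#: Typological affix classes used by the ordering universals.
UNIVERSAL_CLASSES = (
    "derivation",
    "valence",
    "voice",
    "TAM",
    "agreement",
    "number",
    "case",
    "possessive",
    "other",
)

#: A linearized word: left-to-right tuple of morpheme symbols.
SymbolSequence = tuple[str, ...]


@dataclass(frozen=True)
class SlotSpec:
    """One templatic affix slot.

    ``real_rank`` is the attested distance from the root within the slot's
    side: rank 1 is adjacent to the root, larger ranks are further out.
    """

    slot_id: str
    side: str
    real_rank: int
    universal_class: str = "other"

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise ValueError(f"slot {self.slot_id!r}: side must be one of {_SIDES}")
        if self.universal_class not in UNIVERSAL_CLASSES:
            raise ValueError(
                f"slot {self.slot_id!r}: unknown universal class "
                f"{self.universal_class!r}"
            )
        if self.real_rank < 1:
            raise ValueError(f"slot {self.slot_id!r}: real_rank must be >= 1")


@dataclass(frozen=True)
class SlotSchema:
    """A language's affix slot inventory.

    Slot ids are unique and the attested ranks form a contiguous 1..K
    sequence within each side.
    """

    slots: tuple[SlotSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "slots", tuple(self.slots))
        ids = [s.slot_id for s in self.slots]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate slot_id in schema")
        for side in _SIDES:
            ranks = sorted(s.real_rank for s in self.slots if s.side == side)
            if ranks != list(range(1, len(ranks) + 1)):
                raise ValueError(
                    f"real_rank values on side {side!r} must form 1..K, got {ranks}"
                )

    def __getitem__(self, slot_id: str) -> SlotSpec:
        for s in self.slots:
            if s.slot_id == slot_id:
                return s
        raise KeyError(slot_id)

    def __contains__(self, slot_id: str) -> bool:
        return any(s.slot_id == slot_id for s in self.slots)

    def side_slots(self, side: str) -> tuple[SlotSpec, ...]:
        """Slots on one side, in schema order."""
        return tuple(s for s in self.slots if s.side == side)

    @property
    def slot_ids(self) -> tuple[str, ...]:
        return tuple(s.slot_id for s in self.slots)


@dataclass(frozen=True)
class OrderingGrammar:
    """A rank assignment to slots: one total order per side.

    Ranks are distance-from-root coordinates (1 = adjacent to the root) and
    form a permutation of 1..K within each side.  Linear position is derived
    at linearization time, never stored.
    """

    ranks: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ranks", dict(self.ranks))

    def rank(self, slot_id: str) -> int:
        return self.ranks[slot_id]

    def validate(self, schema: SlotSchema) -> None:
        """Raise ``ValueError`` unless this grammar totally orders *schema*."""
        if set(self.ranks) != set(schema.slot_ids):
            raise ValueError("grammar does not cover exactly the schema's slots")
        for side in _SIDES:
            got = sorted(self.ranks[s.slot_id] for s in schema.side_slots(side))
            if got != list(range(1, len(got) + 1)):
                raise ValueError(
                    f"ranks on side {side!r} are not a permutation of 1..K: {got}"
                )

    def rank_vector(self, schema: SlotSchema) -> tuple[int, ...]:
        """Ranks in schema slot order; used for deterministic tie-breaking."""
        return tuple(self.ranks[sid] for sid in schema.slot_ids)

    def side_order(self, schema: SlotSchema, side: str) -> tuple[str, ...]:
        """Slot ids on *side* ordered root-outward (rank 1 first)."""
        slots = schema.side_slots(side)
        return tuple(
            s.slot_id for s in sorted(slots, key=lambda s: self.ranks[s.slot_id])
        )


def real_grammar(schema: SlotSchema) -> OrderingGrammar:
    """The attested ordering: ranks copied from the schema's ``real_rank``."""
    return OrderingGrammar({s.slot_id: s.real_rank for s in schema.slots})


def reverse_grammar(grammar: OrderingGrammar, schema: SlotSchema) -> OrderingGrammar:
    """Reflect each side's order: rank r becomes K_side + 1 - r."""
    grammar.validate(schema)
    ranks: dict[str, int] = {}
    for side in _SIDES:
        slots = schema.side_slots(side)
        k = len(slots)
        for s in slots:
            ranks[s.slot_id] = k + 1 - grammar.ranks[s.slot_id]
    return OrderingGrammar(ranks)


def linearize(word: "MorphWord", grammar: OrderingGrammar) -> SymbolSequence:
    """Linearize *word* under *grammar*.

    Output order: prefix labels outermost-first (rank descending), the root,
    then suffix labels root-outward (rank ascending).  Absent slots
    contribute nothing; no boundary symbols are added here.
    """
    try:
        pre = sorted(word.prefixes, key=lambda a: -grammar.ranks[a.slot_id])
        suf = sorted(word.suffixes, key=lambda a: grammar.ranks[a.slot_id])
    except KeyError as exc:
        raise ValueError(f"affix slot {exc.args[0]!r} missing from grammar") from exc
    return tuple(
        [a.value_label for a in pre] + [word.root] + [a.value_label for a in suf]
    )


def apply_grammar(corpus: "Corpus", grammar: OrderingGrammar) -> list[SymbolSequence]:
    """Linearize every word of *corpus* under *grammar*, preserving order."""
    return [linearize(w, grammar) for w in corpus.words]
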