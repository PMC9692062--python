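"""Reading, writing and summarizing morpheme-segmented corpora.

The authoritative on-disk format is a segmented TSV (one word token per
line) that records the attested root-outward affix order exactly as
written.  CoNLL-U treebanks can also be read, but since CoNLL-U FEATS
carry no linear order, affix order is reconstructed declaratively from the
schema's attested ranks via user-supplied feature rules.

Segmented TSV format (UTF-8):

    id<TAB>root<TAB>affixes

with the ``affixes`` field a ``;``-joined list of ``side:slot=value``
entries, listed root-outward per side, prefixes before suffixes; the field
may be empty for bare stems.
"""

from __future__ import annotations

import fnmatch
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .ordering import PREFIX, SUFFIX, SlotSchema

__all__ = [
    "Affix",
    "MorphWord",
    "Corpus",
    "CorpusSummary",
    "FeatureRule",
    "ParseError",
    "read_segmented_tsv",
    "write_segmented_tsv",
    "read_conllu",
    "corpus_summary",
    "map_rare_roots",
]

_TSV_HEADER = "id\troot\taffixes"
#: characters that may not appear in emitted morpheme symbols
_FORBIDDEN = re.compile(r"[\s;:=]")

UNK_ROOT = "<unk-root>"


class ParseError(ValueError):
    """A malformed corpus file; carries the offending line number."""

    def __init__(self, message: str, path: object = None, line: int | None = None):
        loc = f"{path}:{line}: " if line is not None else ""
        super().__init__(f"{loc}{message}")
        self.line = line


def _check_symbol(sym: str, what: str) -> str:
    if not sym or _FORBIDDEN.search(sym):
        raise ValueError(
            f"{what} {sym!r} must be non-empty and free of whitespace and ';:=' "
        )
    return sym


@dataclass(frozen=True)
class Affix:
    """One affix token: a slot and the morpheme symbol it emits.

    The emitted symbol is the value label (e.g. ``Plural``), not the slot id
    (``Number``); slot ids exist only to define ordering.
    """

    slot_id: str
    value_label: str
    side: str

    def __post_init__(self) -> None:
        _check_symbol(self.value_label, "value_label")
        if self.side not in (PREFIX, SUFFIX):
            raise ValueError(f"bad side {self.side!r}")


@dataclass(frozen=True)
class MorphWord:
    """One word token: root plus templatic affixes per side.

    ``prefixes`` and ``suffixes`` are ordered root-outward (index 0 adjacent
    to the root).  At most one affix per slot.
    """

    root: str
    prefixes: tuple[Affix, ...] = ()
    suffixes: tuple[Affix, ...] = ()
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "prefixes", tuple(self.prefixes))
        object.__setattr__(self, "suffixes", tuple(self.suffixes))
        _check_symbol(self.root, "root")
        for a in self.prefixes:
            if a.side != PREFIX:
                raise ValueError(f"prefix list contains {a.side} affix {a.slot_id!r}")
        for a in self.suffixes:
            if a.side != SUFFIX:
                raise ValueError(f"suffix list contains {a.side} affix {a.slot_id!r}")
        slots = [a.slot_id for a in self.affixes]
        if len(set(slots)) != len(slots):
            raise ValueError(f"duplicate slot in word {self.root!r}: {slots}")

    @property
    def affixes(self) -> tuple[Affix, ...]:
        return self.prefixes + self.suffixes

    def form_key(self) -> tuple:
        """Identity of the fully inflected form (root + slot/value multiset)."""
        return (
            self.root,
            frozenset((a.slot_id, a.value_label) for a in self.affixes),
        )


@dataclass(frozen=True)
class Corpus:
    """A non-empty list of words conforming to one slot schema."""

    words: tuple[MorphWord, ...]
    schema: SlotSchema

    def __post_init__(self) -> None:
        object.__setattr__(self, "words", tuple(self.words))
        if not self.words:
            raise ValueError("corpus must be non-empty")
        for w in self.words:
            for a in w.affixes:
                if a.slot_id not in self.schema:
                    raise ValueError(
                        f"word {w.root!r} uses slot {a.slot_id!r} not in schema"
                    )
                if self.schema[a.slot_id].side != a.side:
                    raise ValueError(
                        f"affix {a.slot_id!r} side {a.side!r} contradicts schema"
                    )

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)


# ---------------------------------------------------------------------------
# segmented TSV


def read_segmented_tsv(path: str | Path, schema: SlotSchema) -> Corpus:
    """Read a segmented TSV corpus; attested affix order is preserved."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError("empty file", path)
    if lines[0].rstrip("\n") != _TSV_HEADER:
        raise ParseError(f"bad header, expected {_TSV_HEADER!r}", path, 1)
    words: list[MorphWord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 3:
            raise ParseError(f"expected 3 columns, got {len(cols)}", path, lineno)
        wid, root, affix_field = cols
        prefixes: list[Affix] = []
        suffixes: list[Affix] = []
        if affix_field:
            for entry in affix_field.split(";"):
                m = re.fullmatch(r"(prefix|suffix):([^:=]+)=([^:=]+)", entry)
                if m is None:
                    raise ParseError(f"malformed affix entry {entry!r}", path, lineno)
                side, slot_id, value = m.groups()
                if slot_id not in schema:
                    raise ParseError(f"unknown slot {slot_id!r}", path, lineno)
                if schema[slot_id].side != side:
                    raise ParseError(
                        f"slot {slot_id!r} is a {schema[slot_id].side}, "
                        f"written as {side}",
                        path,
                        lineno,
                    )
                (prefixes if side == PREFIX else suffixes).append(
                    Affix(slot_id, value, side)
                )
        try:
            words.append(
                MorphWord(root, tuple(prefixes), tuple(suffixes), source_id=wid)
            )
        except ValueError as exc:
            raise ParseError(str(exc), path, lineno) from exc
    if not words:
        raise ParseError("no word records in file", path)
    return Corpus(tuple(words), schema)


def write_segmented_tsv(corpus: Corpus, path: str | Path) -> None:
    """Write *corpus* in the segmented TSV format (deterministic bytes)."""
    out = [_TSV_HEADER]
    for i, w in enumerate(corpus.words):
        entries = [f"{a.side}:{a.slot_id}={a.value_label}" for a in w.affixes]
        wid = w.source_id or f"w{i + 1}"
        out.append(f"{wid}\t{w.root}\t{';'.join(entries)}")
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# CoNLL-U


@dataclass(frozen=True)
class FeatureRule:
    """Map one FEATS key/value onto a slot and an emitted value label.

    ``value_pattern`` is an ``fnmatch``-style glob matched against the
    feature value (``*`` matches any value).
    """

    feature: str
    value_pattern: str
    slot_id: str
    value_label: str | None = None  # None: use the matched feature value

    def matches(self, key: str, value: str) -> bool:
        return key == self.feature and fnmatch.fnmatchcase(value, self.value_pattern)

    def label_for(self, value: str) -> str:
        return self.value_label if self.value_label is not None else value


def read_conllu(
    path: str | Path,
    schema: SlotSchema,
    pos_filter: set[str],
    feature_rules: Sequence[FeatureRule],
    *,
    include_bare: bool = False,
) -> Corpus:
    """Extract a morpheme-segmented corpus from a CoNLL-U treebank.

    One :class:`MorphWord` is produced per token whose UPOS is in
    *pos_filter* and that matches at least one rule; the root is the lemma.
    Affix order within a side follows the schema's attested ranks, since
    FEATS pairs are unordered.  Tokens matching no rule are bare stems and
    are excluded unless *include_bare* is set (the analysis targets
    inflected tokens).
    """
    path = Path(path)
    for rule in feature_rules:
        if rule.slot_id not in schema:
            raise ValueError(f"feature rule references unknown slot {rule.slot_id!r}")
    words: list[MorphWord] = []
    for lineno, line in enumerate(
        path.read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ParseError(f"expected 10 columns, got {len(cols)}", path, lineno)
        tid, _form, lemma, upos, _xpos, feats = cols[:6]
        if "-" in tid or "." in tid:  # multiword ranges / empty nodes
            continue
        if upos not in pos_filter:
            continue
        pairs: list[tuple[str, str]] = []
        if feats not in ("", "_"):
            for item in feats.split("|"):
                if "=" not in item:
                    raise ParseError(f"malformed FEATS item {item!r}", path, lineno)
                k, v = item.split("=", 1)
                pairs.append((k, v))
        by_slot: dict[str, Affix] = {}
        for k, v in pairs:
            for rule in feature_rules:
                if rule.matches(k, v):
                    if rule.slot_id not in by_slot:  # first match wins
                        spec = schema[rule.slot_id]
                        by_slot[rule.slot_id] = Affix(
                            rule.slot_id, rule.label_for(v), spec.side
                        )
                    break
        if not by_slot and not include_bare:
            continue
        prefixes = sorted(
            (a for a in by_slot.values() if a.side == PREFIX),
            key=lambda a: schema[a.slot_id].real_rank,
        )
        suffixes = sorted(
            (a for a in by_slot.values() if a.side == SUFFIX),
            key=lambda a: schema[a.slot_id].real_rank,
        )
        words.append(
            MorphWord(
                lemma, tuple(prefixes), tuple(suffixes), source_id=f"{path.name}:{lineno}"
            )
        )
    if not words:
        raise ParseError("no matching tokens in file", path)
    return Corpus(tuple(words), schema)


# ---------------------------------------------------------------------------
# summaries and variance control


@dataclass(frozen=True)
class CorpusSummary:
    n_tokens: int
    n_types: int
    per_slot_counts: dict[str, int] = field(default_factory=dict)


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Token/type counts and per-slot attestation counts."""
    slot_counts: Counter[str] = Counter()
    types = set()
    for w in corpus.words:
        types.add(w.form_key())
        for a in w.affixes:
            slot_counts[a.slot_id] += 1
    per_slot = {s.slot_id: slot_counts.get(s.slot_id, 0) for s in corpus.schema.slots}
    return CorpusSummary(len(corpus.words), len(types), per_slot)


def map_rare_roots(corpus: Corpus, min_count: int = 2) -> Corpus:
    """Replace roots attested fewer than *min_count* times by a shared symbol.

    Off by default throughout the pipeline; a variance-control option for
    plug-in estimation on real corpora with long lexical tails.
    """
    counts = Counter(w.root for w in corpus.words)
    words = tuple(
        w
        if counts[w.root] >= min_count
        else MorphWord(UNK_ROOT, w.prefixes, w.suffixes, w.source_id)
        for w in corpus.words
    )
    return Corpus(words, corpus.schema)
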