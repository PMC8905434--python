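"""Core containers shared across the pipeline.

The text model is deliberately simple: a *word* is a run of non-space
characters, a *sequence* is a list of words rendered as a single string in
which every word (including the last) is followed by exactly one space.  The
trailing space is a boundary marker owned by the preceding word: segmentation
units that end at a word boundary own that space in their span, which makes
word-final units (``"do "``) distinct from word prefixes (``"do"`` inside
``"down"``) and makes segmentation coverage exact at the character level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "Word",
    "Sequence",
    "Corpus",
    "UnitToken",
    "SegmentationResult",
    "FixationTable",
    "effective_length",
]


def effective_length(form: str) -> int:
    """Length of a unit form excluding its trailing space marker.

    Internal spaces of multiword units count toward the length (the unit
    ``"i have"`` has effective length 6); only the single trailing boundary
    space is excluded.
    """
    return len(form) - 1 if form.endswith(" ") else len(form)


@dataclass(frozen=True)
class Word:
    """A single space-delimited word token (lowercase, no internal space)."""

    text: str

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("word text must be non-empty")
        if " " in self.text:
            raise ValueError(f"word text contains a space: {self.text!r}")
        if self.text != self.text.lower():
            raise ValueError(f"word text must be lowercase: {self.text!r}")
        if self.text[0] == "'":
            raise ValueError(f"apostrophe at word start: {self.text!r}")

    @property
    def length(self) -> int:
        return len(self.text)


class Sequence:
    """An ordered run of words with an exact character-offset rendering.

    ``rendered`` is the words joined by single spaces plus one trailing
    space; ``offsets`` holds per-word half-open character spans into
    ``rendered`` (spans exclude the following space).
    """

    __slots__ = ("words", "seq_id", "rendered", "offsets")

    def __init__(self, words: Iterable[Word], seq_id: str = "") -> None:
        self.words: tuple[Word, ...] = tuple(words)
        if not self.words:
            raise ValueError("sequence must contain at least one word")
        self.seq_id = seq_id
        parts: list[str] = []
        offsets: list[tuple[int, int]] = []
        pos = 0
        for w in self.words:
            offsets.append((pos, pos + len(w.text)))
            parts.append(w.text)
            pos += len(w.text) + 1
        self.rendered: str = " ".join(parts) + " "
        self.offsets: tuple[tuple[int, int], ...] = tuple(offsets)

    @classmethod
    def from_texts(cls, texts: Iterable[str], seq_id: str = "") -> "Sequence":
        return cls((Word(t) for t in texts), seq_id)

    def __len__(self) -> int:
        return len(self.words)

    def __repr__(self) -> str:
        return f"Sequence({self.seq_id!r}, {self.rendered!r})"


@dataclass
class Corpus:
    """An ordered collection of non-empty sequences."""

    sequences: list[Sequence]
    source_id: str = ""

    def __post_init__(self) -> None:
        for s in self.sequences:
            if len(s) == 0:
                raise ValueError("corpus contains an empty sequence")

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self.sequences)

    @property
    def n_words(self) -> int:
        return sum(len(s) for s in self.sequences)


@dataclass
class UnitToken:
    """One segmented unit token: its surface form and character span.

    The form equals the rendered substring at ``span`` and includes the
    absorbed trailing space when the unit ends at a word boundary.
    """

    form: str
    span: tuple[int, int]

    @property
    def effective_length(self) -> int:
        return effective_length(self.form)


@dataclass
class SegmentationResult:
    """Segmentation of one sequence into contiguous unit tokens.

    ``verdicts`` records, in order, the counterfactual evaluation outcomes
    for the largest candidate at each evaluated choice point (form, "good" or
    "bad").  ``choice_counts`` holds the (selected, rejected) lookahead token
    counts of each evaluated choice, for diagnostics and invariant checks.
    """

    tokens: list[UnitToken]
    novel_symbols: list[str] = field(default_factory=list)
    verdicts: list[tuple[str, str]] = field(default_factory=list)
    choice_counts: list[tuple[int, int]] = field(default_factory=list)

    @property
    def token_count(self) -> int:
        return len(self.tokens)

    def concatenated(self) -> str:
        return "".join(t.form for t in self.tokens)

    def covers(self, rendered: str) -> bool:
        return self.concatenated() == rendered


class FixationTable:
    """Per-word integer first-pass fixation counts, observed or predicted.

    Entries are keyed by ``(sequence_id, word_index)`` and store the word
    form alongside its count.
    """

    def __init__(self) -> None:
        self._entries: dict[tuple[str, int], tuple[str, int]] = {}

    def set(self, seq_id: str, word_index: int, word: str, count: int) -> None:
        if count < 0:
            raise ValueError(
                f"negative fixation count {count} for {(seq_id, word_index)}"
            )
        self._entries[(seq_id, word_index)] = (word, int(count))

    def get(self, seq_id: str, word_index: int) -> int:
        return self._entries[(seq_id, word_index)][1]

    def word(self, seq_id: str, word_index: int) -> str:
        return self._entries[(seq_id, word_index)][0]

    def keys(self) -> list[tuple[str, int]]:
        return list(self._entries)

    def items(self) -> list[tuple[tuple[str, int], tuple[str, int]]]:
        return list(self._entries.items())

    def counts(self) -> list[int]:
        return [c for (_, c) in self._entries.values()]

    def total(self) -> int:
        return sum(self.counts())

    def update(self, other: "FixationTable") -> None:
        self._entries.update(other._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._entries

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FixationTable):
            return NotImplemented
        return self._entries == other._entries

    def copy(self) -> "FixationTable":
        t = FixationTable()
        t._entries = dict(self._entries)
        return t
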