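"""Text normalization and sequence splitting.

Raw text is lowercased, diacritics are stripped by canonical decomposition,
and every punctuation character becomes a sequence *divider*: punctuation
marks the end of an input sequence rather than being part of one.  The only
exception is an apostrophe flanked by word characters on both sides
(possessives and contractions such as ``john's`` or ``don't``), which stays
inside the word.  Line breaks in display-formatted material also divide
sequences: words on different display lines are too far apart to be read as
one unit.
"""

from __future__ import annotations

import unicodedata
from pathlib import Path

from .core import Corpus, FixationTable, Sequence, Word

#: Reserved divider character inserted by :func:`normalize_text` wherever
#: punctuation divided the input.
DIVIDER = "⟂"  # ⟂

_APOSTROPHES = {"'", "’"}


def normalize_text(raw: str) -> str:
    """Normalize raw text to the model alphabet.

    Lowercases, removes diacritics (canonical decomposition, then dropping
    combining marks, e.g. ``ë → e``), replaces punctuation with the reserved
    divider, keeps intra-word apostrophes, and collapses whitespace runs to
    single spaces.  Empty input yields empty output.
    """
    s = unicodedata.normalize("NFD", raw.lower())
    s = "".join(ch for ch in s if not unicodedata.combining(ch))
    out: list[str] = []
    n = len(s)
    for i, ch in enumerate(s):
        if ch in _APOSTROPHES:
            prev_ok = i > 0 and s[i - 1].isalnum()
            next_ok = i + 1 < n and s[i + 1].isalnum()
            out.append("'" if (prev_ok and next_ok) else f" {DIVIDER} ")
        elif ch.isspace():
            out.append(" ")
        elif ch.isalnum():
            out.append(ch)
        else:
            out.append(f" {DIVIDER} ")
    return " ".join("".join(out).split())


def split_sequences(
    normalized: str,
    line_break_positions: tuple[int, ...] | list[int] = (),
    source_id: str = "",
    start_index: int = 0,
) -> Corpus:
    """Split normalized text into a corpus of word sequences.

    Both divider characters and the supplied line-break character positions
    split the text; empty fragments are dropped and each fragment is
    tokenized on spaces.  Sequence ids are ``s<k>`` with ``k`` counting from
    ``start_index``.
    """
    cuts = sorted(set(p for p in line_break_positions if 0 < p < len(normalized)))
    pieces: list[str] = []
    prev = 0
    for p in cuts:
        pieces.append(normalized[prev:p])
        prev = p
    pieces.append(normalized[prev:])

    sequences: list[Sequence] = []
    k = start_index
    for piece in pieces:
        for fragment in piece.split(DIVIDER):
            texts = fragment.split()
            if not texts:
                continue
            sequences.append(Sequence.from_texts(texts, seq_id=f"s{k}"))
            k += 1
    return Corpus(sequences, source_id=source_id)


def render(sequence: Sequence) -> str:
    """Words joined by single spaces plus one trailing space."""
    return sequence.rendered


def read_corpus(path: str | Path, source_id: str | None = None) -> Corpus:
    """Read a plain-text corpus, one display line per physical line.

    Each line is normalized and split independently, so line breaks always
    divide sequences.
    """
    path = Path(path)
    sequences: list[Sequence] = []
    k = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            sub = split_sequences(normalize_text(line), start_index=k)
            sequences.extend(sub.sequences)
            k += len(sub.sequences)
    return Corpus(sequences, source_id=source_id or path.name)


def write_sequences(corpus: Corpus, path: str | Path) -> None:
    """Write one rendered sequence per line."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for seq in corpus:
            fh.write(seq.rendered + "\n")


_FIX_HEADER = ["sequence_id", "word_index", "word", "fixation_count"]


def read_fixation_table(path: str | Path) -> FixationTable:
    """Read a per-word fixation-count TSV.

    Expects a header line ``sequence_id\tword_index\tword\tfixation_count``.
    Malformed rows raise :class:`ValueError` naming the line number; negative
    counts raise a validation error.
    """
    table = FixationTable()
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _FIX_HEADER:
            raise ValueError(
                f"{path}: expected header {_FIX_HEADER}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            seq_id, idx_s, word, count_s = fields
            try:
                idx = int(idx_s)
                count = int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative fixation count {count}")
            table.set(seq_id, idx, word, count)
    return table


def write_fixation_table(table: FixationTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_FIX_HEADER) + "\n")
        for (seq_id, idx), (word, count) in sorted(table.items()):
            fh.write(f"{seq_id}\t{idx}\t{word}\t{count}\n")
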