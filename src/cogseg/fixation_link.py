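"""Linking hypothesis between segmentations and eye fixations.

Each segmented unit is assumed to receive exactly one first-pass fixation at
the center of its character span (trailing boundary space excluded, internal
spaces included).  A word's predicted fixation count is the number of units
centered on it: a multiword unit such as ``"i have"`` (center between *h*
and *a*) predicts zero fixations on *i* — the word is skipped — and one on
*have*; a word split into two subword units predicts two fixations.

When a center falls exactly on an inter-word space or on the boundary
between two words, the fixation is credited to the word contributing more
characters to the unit, with ties broken toward the right-hand word
(a forward-saccade bias).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence as TSequence

from .core import Corpus, FixationTable, SegmentationResult, Sequence, UnitToken

LABEL_SKIP = "Skip"
LABEL_ONE = "One"
LABEL_MORE = "More"
LABELS3 = (LABEL_SKIP, LABEL_ONE, LABEL_MORE)


@dataclass(frozen=True)
class UnitCenter:
    """Center locus of a unit: a character index for odd effective lengths,
    or a half-integer boundary between two adjacent characters for even
    effective lengths."""

    span: tuple[int, int]
    effective_length: int
    locus: float  # character index (int-valued) or boundary (half-integer)

    @property
    def on_boundary(self) -> bool:
        return self.locus != int(self.locus)


def unit_center(token: UnitToken) -> UnitCenter:
    """Center of a unit's effective span (trailing space excluded)."""
    start, end = token.span
    eff_end = end - 1 if token.form.endswith(" ") else end
    eff_len = eff_end - start
    return UnitCenter(token.span, eff_len, start + (eff_len - 1) / 2.0)


def _assign_word(
    token: UnitToken,
    center: UnitCenter,
    word_of: list[int],
    offsets: TSequence[tuple[int, int]],
) -> int:
    """Word index receiving the unit's fixation."""
    c = center.locus
    if c == int(c):
        ci = int(c)
        wi = word_of[ci]
        if wi >= 0:
            return wi
        left, right = word_of[ci - 1], word_of[ci + 1]
    else:
        c1, c2 = int(c - 0.5), int(c + 0.5)
        w1, w2 = word_of[c1], word_of[c2]
        if w1 == w2:
            return w1
        if w1 < 0:
            left, right = word_of[c1 - 1], w2
        else:
            left, right = w1, word_of[c2 + 1]
    # center at a word boundary: credit the word with more unit characters
    start, end = center.span
    eff_end = start + center.effective_length

    def overlap(wi: int) -> int:
        ws, we = offsets[wi]
        return max(0, min(eff_end, we) - max(start, ws))

    return right if overlap(right) >= overlap(left) else left


def predict_fixation_counts(
    segmentation: SegmentationResult, sequence: Sequence
) -> FixationTable:
    """Per-word predicted first-pass fixation counts for one sequence.

    Each unit contributes exactly one fixation to the word containing its
    center, so the counts sum to the segmentation's token count.
    """
    rendered = sequence.rendered
    if not segmentation.covers(rendered):
        raise ValueError("segmentation does not cover the sequence")
    word_of = [-1] * len(rendered)
    for wi, (s, e) in enumerate(sequence.offsets):
        for p in range(s, e):
            word_of[p] = wi
    counts = [0] * len(sequence.words)
    for token in segmentation.tokens:
        counts[_assign_word(token, unit_center(token), word_of, sequence.offsets)] += 1
    table = FixationTable()
    for i, w in enumerate(sequence.words):
        table.set(sequence.seq_id, i, w.text, counts[i])
    return table


def predict_corpus_fixations(
    segmentations: TSequence[SegmentationResult], corpus: Corpus
) -> FixationTable:
    """Predicted counts for a whole corpus (segmentations aligned with it)."""
    if len(segmentations) != len(corpus.sequences):
        raise ValueError("one segmentation per sequence is required")
    table = FixationTable()
    for seg, seq in zip(segmentations, corpus):
        table.update(predict_fixation_counts(seg, seq))
    return table


def align_reference_words(
    model_counts: FixationTable,
    groups: Iterable[tuple[tuple[str, int], str, list[tuple[str, int]]]],
) -> FixationTable:
    """Sum model-word counts onto reference words.

    ``groups`` maps each reference word — ``(reference key, reference word
    form, model keys)`` — to the model words it spans; a hyphenated source
    token split into several model words gets the sum of their counts, and
    unhyphenated words map one-to-one.  A model key absent from
    ``model_counts`` raises :class:`KeyError` naming it.
    """
    out = FixationTable()
    for (ref_seq, ref_idx), ref_word, model_keys in groups:
        total = 0
        for key in model_keys:
            if key not in model_counts:
                raise KeyError(f"unalignable model word at {key}")
            total += model_counts.get(*key)
        out.set(ref_seq, ref_idx, ref_word, total)
    return out


def label3(count: int) -> str:
    """Collapse a fixation count to Skip (0) / One (1) / More (>1)."""
    if count < 0:
        raise ValueError(f"negative fixation count {count}")
    if count == 0:
        return LABEL_SKIP
    if count == 1:
        return LABEL_ONE
    return LABEL_MORE


def mean_observed_unit_length(observed: FixationTable, corpus: Corpus) -> float:
    """Mean length of the inferred observed fixation units, in characters.

    Fixations are assumed to sit at the centers of the units they reveal, so
    within a sequence the mean unit length is the rendered length (one
    inter-word space per boundary included) divided by the total fixation
    count.  The corpus value is the fixation-count-weighted mean over
    sequences; sequences with zero fixations are excluded.
    """
    num = 0
    den = 0
    for seq in corpus:
        total = sum(
            observed.get(seq.seq_id, i) for i in range(len(seq.words))
        )
        if total == 0:
            continue
        num += len(seq.rendered)
        den += total
    if den == 0:
        raise ValueError("no fixations observed in the corpus")
    return num / den


def infer_fixation_unit_lengths(
    observed: FixationTable, corpus: Corpus
) -> list[float]:
    """Secondary, boundary-construction estimator of observed unit lengths.

    Within each word, its k fixations are placed at the centers of k equal
    sub-spans; unit boundaries are then drawn midway between consecutive
    fixation positions of the sequence (and at the sequence edges), and the
    gaps between boundaries are the unit lengths.  This is a coarser
    operationalization than the ratio in :func:`mean_observed_unit_length`
    and is provided for comparison only.
    """
    lengths: list[float] = []
    for seq in corpus:
        positions: list[float] = []
        for i, (s, e) in enumerate(seq.offsets):
            k = observed.get(seq.seq_id, i)
            width = e - s
            for j in range(k):
                positions.append(s + width * (2 * j + 1) / (2 * k))
        if not positions:
            continue
        bounds = [0.0]
        for a, b in zip(positions, positions[1:]):
            bounds.append((a + b) / 2.0)
        bounds.append(float(len(seq.rendered)))
        lengths.extend(b - a for a, b in zip(bounds, bounds[1:]))
    return lengths
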