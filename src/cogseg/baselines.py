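"""Word-based baselines for fixation prediction.

*Word-by-Word* assumes the cognitive units are exactly the words: one
fixation per word.  *Only-Length* assumes the number of fixations on a word
is determined solely by its length: it shuffles the observed counts among
words with the same number of letters, destroying every non-length signal
(frequency, morphology, position) while preserving the per-length count
distribution exactly.
"""

from __future__ import annotations

import numpy as np

from .core import Corpus, FixationTable


def predict_word_by_word(corpus: Corpus) -> FixationTable:
    """Exactly one predicted fixation on every word."""
    table = FixationTable()
    for seq in corpus:
        for i, w in enumerate(seq.words):
            table.set(seq.seq_id, i, w.text, 1)
    return table


def predict_only_length(
    observed: FixationTable, corpus: Corpus, seed: int = 0
) -> FixationTable:
    """Permute observed counts uniformly at random within each word-length
    group (length = number of letters, trailing space excluded).

    Every word of the corpus must be covered by ``observed``; the per-group
    multiset of counts is preserved exactly.  Deterministic under ``seed``.
    """
    groups: dict[int, list[tuple[str, int, str, int]]] = {}
    for seq in corpus:
        for i, w in enumerate(seq.words):
            key = (seq.seq_id, i)
            if key not in observed:
                raise KeyError(
                    f"no observed fixation count for word {w.text!r} at {key}"
                )
            groups.setdefault(w.length, []).append(
                (seq.seq_id, i, w.text, observed.get(seq.seq_id, i))
            )

    rng = np.random.default_rng(seed)
    table = FixationTable()
    for length in sorted(groups):
        members = groups[length]
        counts = [c for (_, _, _, c) in members]
        perm = rng.permutation(len(members))
        for (seq_id, i, word, _), j in zip(members, perm):
            table.set(seq_id, i, word, counts[j])
    return table
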