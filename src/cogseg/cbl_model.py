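"""Chunk-Based Learner (CBL) comparator.

CBL is a frequentist, word-level chunker: every word starts out as a chunk,
and whenever the backward transitional probability (BTP) of the current
chunk pair rises above the running average of all BTPs evaluated so far, the
pair is merged into a new chunk that replaces the pair in further
processing.  Chunks therefore grow hierarchically (a chunk of a chunk yields
a trigram and beyond).  The model has no tunable hyperparameters: its
threshold is the running average itself.

At test time the learned inventory is frozen and sequences are segmented by
greedy left-to-right longest match over whole words; CBL never produces
subword units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .core import Corpus, SegmentationResult, Sequence, UnitToken


@dataclass
class CBLState:
    """Incremental learner state: chunk counts, pair counts, the running
    average of evaluated BTPs, and the multiword chunk inventory."""

    unigrams: Counter = field(default_factory=Counter)
    bigrams: Counter = field(default_factory=Counter)
    btp_sum: float = 0.0
    btp_n: int = 0
    inventory: set[str] = field(default_factory=set)
    max_chunk_words: int = 1

    @property
    def running_average(self) -> float | None:
        """Mean of all BTP values evaluated so far; None before the first."""
        if self.btp_n == 0:
            return None
        return self.btp_sum / self.btp_n


def btp(state: CBLState, left: str, right: str) -> float:
    """Backward transitional probability count(left, right) / count(right)."""
    denom = state.unigrams[right]
    if denom == 0:
        raise ValueError(f"right chunk {right!r} has never been observed")
    return state.bigrams[(left, right)] / denom


def observe_sequence(state: CBLState, sequence: Sequence) -> CBLState:
    """One incremental left-to-right learning pass over a sequence.

    Counts are updated word by word; when the current pair's BTP exceeds the
    running average the pair becomes a new chunk which replaces it in
    further processing.  The running average is updated after every BTP
    evaluation.  Before the first evaluation the average is undefined and
    the comparison is treated as "not above average".
    """
    words = [w.text for w in sequence.words]
    current = words[0]
    state.unigrams[current] += 1
    for w in words[1:]:
        state.unigrams[w] += 1
        state.bigrams[(current, w)] += 1
        p = btp(state, current, w)
        avg = state.running_average
        above = avg is not None and p > avg
        state.btp_sum += p
        state.btp_n += 1
        if above:
            chunk = f"{current} {w}"
            state.inventory.add(chunk)
            state.unigrams[chunk] += 1
            state.max_chunk_words = max(state.max_chunk_words, chunk.count(" ") + 1)
            current = chunk
        else:
            current = w
    return state


def train_cbl(corpus: Corpus, passes: int = 1) -> CBLState:
    """Learn the training corpus (a single incremental pass by default)."""
    state = CBLState()
    for _ in range(passes):
        for seq in corpus:
            observe_sequence(state, seq)
    return state


def segment_frozen(state: CBLState, sequence: Sequence) -> SegmentationResult:
    """Segment with a fixed inventory: greedy left-to-right longest match of
    multiword chunks over the word sequence; unmatched words are emitted as
    single-word tokens.  Token spans always align to word boundaries."""
    words = [w.text for w in sequence.words]
    rendered = sequence.rendered
    offsets = sequence.offsets
    tokens: list[UnitToken] = []
    i = 0
    n = len(words)
    while i < n:
        take = 1
        for k in range(min(state.max_chunk_words, n - i), 1, -1):
            if " ".join(words[i : i + k]) in state.inventory:
                take = k
                break
        start = offsets[i][0]
        end = offsets[i + take - 1][1] + 1  # own the boundary space
        tokens.append(UnitToken(rendered[start:end], (start, end)))
        i += take
    return SegmentationResult(tokens=tokens)


def segment_corpus_frozen(state: CBLState, corpus: Corpus) -> list[SegmentationResult]:
    return [segment_frozen(state, seq) for seq in corpus]


def inventory_to_file(state: CBLState, path: str | Path) -> None:
    """One chunk per line with its final count, spaces rendered as ``␣``."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# cogseg cbl inventory v1\n")
        for chunk in sorted(state.inventory):
            fh.write(f"{chunk.replace(' ', '␣')}\t{state.unigrams[chunk]}\n")


def inventory_from_file(path: str | Path) -> CBLState:
    state = CBLState()
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") or not line:
                continue
            chunk_enc, count_s = line.split("\t")
            chunk = chunk_enc.replace("␣", " ")
            state.inventory.add(chunk)
            state.unigrams[chunk] = int(count_s)
            state.max_chunk_words = max(state.max_chunk_words, chunk.count(" ") + 1)
    return state
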