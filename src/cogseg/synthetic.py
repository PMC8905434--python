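"""Synthetic corpora with known cognitive-unit structure.

The generator emulates the statistical skeleton the segmentation models
assume: a ground-truth inventory of chunk types — plain words, multiword
collocations (pairs/triples of inventory words), and composite words built
from two subword pieces — sampled with Zipfian token frequencies into
sequences.  The generating chunk boundaries are recorded as the true
segmentation, and "observed" fixation tables are produced from it by the
unit-center linking rule, optionally with symmetric ±1 count noise.

Multiword and composite chunks are interleaved among the top Zipf ranks so
that supra-word and subword structure is frequent enough to be learnable at
small corpus sizes, mirroring the high token frequencies of natural
collocations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Corpus, FixationTable, SegmentationResult, Sequence, UnitToken
from .fixation_link import predict_corpus_fixations

KIND_WORD = "word"
KIND_MULTIWORD = "multiword"
KIND_SUBWORD = "subword"


@dataclass(frozen=True)
class ChunkSpec:
    """One generative chunk: its kind, surface text (spaces between words,
    no trailing space) and the true unit forms it contributes."""

    kind: str
    text: str
    units: tuple[str, ...]


@dataclass
class ChunkInventory:
    """Ground-truth generative unit set with Zipfian sampling weights."""

    chunks: list[ChunkSpec]
    weights: np.ndarray
    words: list[str]
    seed: int

    def target_forms(self, kinds: tuple[str, ...]) -> list[str]:
        """Unit forms of the selected chunk kinds, as they appear in a true
        segmentation (multiword chunks carry their trailing space)."""
        forms: list[str] = []
        for spec in self.chunks:
            if spec.kind in kinds:
                forms.extend(spec.units)
        return forms


@dataclass
class SynthConfig:
    """Study conditions for the synthetic corpora.

    Defaults follow the parameter-recovery setting: 20 high-frequency
    multiword chunks under a Zipf(s=1) token distribution over 2,000
    sequences, a 12-letter alphabet, and word lengths of 2-7 characters.
    """

    n_words: int = 40
    n_multiword: int = 20
    n_composite: int = 6
    zipf_s: float = 1.0
    n_sequences: int = 2000
    chunks_per_seq: tuple[int, int] = (4, 12)
    noise: float = 0.0
    seed: int = 0
    alphabet_size: int = 12
    word_len: tuple[int, int] = (2, 7)
    piece_len: tuple[int, int] = (2, 4)

    def __post_init__(self) -> None:
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be a probability")
        if min(self.n_words, self.n_sequences) < 1:
            raise ValueError("counts must be positive")


def _unique_strings(
    rng: np.random.Generator,
    n: int,
    length_range: tuple[int, int],
    alphabet: str,
    taken: set[str],
) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        s = "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))
        if s not in taken:
            taken.add(s)
            out.append(s)
    return out


def make_inventory(config: SynthConfig) -> ChunkInventory:
    """Build a chunk inventory; deterministic under the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"[: config.alphabet_size]
    taken: set[str] = set()

    words = _unique_strings(rng, config.n_words, config.word_len, alphabet, taken)
    word_specs = [ChunkSpec(KIND_WORD, w, (w + " ",)) for w in words]

    multi_specs: list[ChunkSpec] = []
    seen_multi: set[str] = set()
    while len(multi_specs) < config.n_multiword:
        k = int(rng.integers(2, 4))  # pairs and triples
        idx = rng.choice(config.n_words, size=k, replace=False)
        text = " ".join(words[i] for i in idx)
        if text in seen_multi:
            continue
        seen_multi.add(text)
        multi_specs.append(ChunkSpec(KIND_MULTIWORD, text, (text + " ",)))

    composite_specs: list[ChunkSpec] = []
    pieces = _unique_strings(
        rng, 2 * config.n_composite, config.piece_len, alphabet, taken
    )
    for j in range(config.n_composite):
        p1, p2 = pieces[2 * j], pieces[2 * j + 1]
        composite_specs.append(
            ChunkSpec(KIND_SUBWORD, p1 + p2, (p1, p2 + " "))
        )

    # Interleave kinds round-robin so multiword/composite chunks sit at
    # high Zipf ranks (frequent collocations), words fill the tail.
    pools = [list(word_specs), list(multi_specs), list(composite_specs)]
    chunks: list[ChunkSpec] = []
    while any(pools):
        for pool in pools:
            if pool:
                chunks.append(pool.pop(0))

    ranks = np.arange(1, len(chunks) + 1, dtype=float)
    weights = ranks ** (-config.zipf_s)
    weights /= weights.sum()
    return ChunkInventory(chunks, weights, words, config.seed)


def sample_corpus(
    inventory: ChunkInventory, config: SynthConfig
) -> tuple[Corpus, list[SegmentationResult]]:
    """Sample sequences of Zipf-weighted chunks, recording the generating
    chunk boundaries as the true segmentation."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lo, hi = config.chunks_per_seq
    sequences: list[Sequence] = []
    true_segs: list[SegmentationResult] = []
    n_chunks = len(inventory.chunks)
    for s in range(config.n_sequences):
        k = int(rng.integers(lo, hi + 1))
        idx = rng.choice(n_chunks, size=k, p=inventory.weights)
        texts: list[str] = []
        tokens: list[UnitToken] = []
        pos = 0
        for ci in idx:
            spec = inventory.chunks[ci]
            if spec.kind == KIND_SUBWORD:
                p1, p2 = spec.units[0], spec.units[1][:-1]
                texts.append(p1 + p2)
                tokens.append(UnitToken(p1, (pos, pos + len(p1))))
                tokens.append(
                    UnitToken(p2 + " ", (pos + len(p1), pos + len(p1) + len(p2) + 1))
                )
                pos += len(spec.text) + 1
            else:
                texts.extend(spec.text.split(" "))
                tokens.append(UnitToken(spec.text + " ", (pos, pos + len(spec.text) + 1)))
                pos += len(spec.text) + 1
        seq = Sequence.from_texts(texts, seq_id=f"s{s}")
        assert len(seq.rendered) == pos
        sequences.append(seq)
        true_segs.append(SegmentationResult(tokens=tokens))
    return Corpus(sequences, source_id="synthetic"), true_segs


def synth_fixations(
    corpus: Corpus,
    true_segs: list[SegmentationResult],
    noise: float = 0.0,
    seed: int = 0,
) -> FixationTable:
    """Observed-style fixation counts from the true segmentation via the
    unit-center rule; with probability ``noise`` a word's count is perturbed
    by ±1 (reflected at zero, so a perturbed count always changes and the
    nominal noise rate is exact)."""
    table = predict_corpus_fixations(true_segs, corpus)
    if noise > 0.0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        for key, (word, count) in sorted(table.items()):
            if rng.random() < noise:
                delta = 1 if rng.random() < 0.5 else -1
                if count == 0:
                    delta = 1
                table.set(key[0], key[1], word, count + delta)
    return table


def lexicon_recall(
    trained,
    inventory: ChunkInventory,
    top_fraction: float,
    kinds: tuple[str, ...] = (KIND_MULTIWORD, KIND_SUBWORD),
) -> float:
    """Share of the inventory's multiword/subword unit forms present in the
    top ``top_fraction`` of the trained lexicon (by rank)."""
    targets = inventory.target_forms(kinds)
    if not targets:
        raise ValueError("inventory has no chunks of the requested kinds")
    top = set(trained.top_fraction(top_fraction))
    return sum(1 for f in targets if f in top) / len(targets)


def write_true_segmentations(
    true_segs: list[SegmentationResult], path
) -> None:
    from .segio import write_segmentations

    write_segmentations(true_segs, path)
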