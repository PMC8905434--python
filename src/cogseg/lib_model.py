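"""The Less-is-Better (LiB) chunk learner.

LiB learns an ordered lexicon of unit types from raw character input under a
least-effort objective: minimize the number of unit *tokens* needed to cover
the input (working-memory load) while keeping the number of unit *types*
small (long-term-memory load).  No frequency statistics are stored; a type's
rank in the lexicon encodes its likelihood of being a genuine cognitive unit.

Segmentation is greedy larger-first with a counterfactual check: at each
position the largest matching type is provisionally chosen, then evaluated by
comparing the token count of the input segmented with it against the count
obtained when it is ignored (so the second-largest match is used instead).
If the largest type produces strictly more tokens it is judged *Bad* and the
runner-up is selected; otherwise it is judged *Good*.

Learning interleaves four mechanisms per epoch: *memorizing* (randomly
sampled adjacent token pairs are concatenated into new types, appended at the
lowest rank), *re-ranking* (Good types move toward the front, Bad types
toward the back), and *forgetting* (types lingering in the tail of the
lexicon without a Good verdict are removed after a probation period).
Training stops when the Shannon encoding length of a batch stops improving.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence as TSequence

import numpy as np

from .core import (
    Corpus,
    SegmentationResult,
    Sequence,
    UnitToken,
    effective_length,
)

VERDICT_NONE = "none"
VERDICT_GOOD = "good"
VERDICT_BAD = "bad"


@dataclass
class LiBConfig:
    """Hyperparameters of the LiB learner.

    batch_size
        Sequences per training epoch (sampled with replacement unless
        training in large-corpus mode).
    p_memorize
        Probability that an adjacent token pair is memorized as a new type.
    promote_factor, demote_factor
        Rank multipliers for Good / Bad re-ranking moves (clamped to the
        lexicon bounds).
    probation_zone
        Tail fraction of the lexicon under probation each epoch.
    probation_period
        Epochs a tail entry survives without a Good verdict before removal.
    stop_patience
        Epochs without a new encoding-bits minimum before training stops.
    max_unit_len
        Upper limit on a unit's effective length (characters, internal
        spaces included, trailing space excluded); ``None`` = unbounded.
    """

    batch_size: int = 200
    p_memorize: float = 0.1
    promote_factor: float = 0.5
    demote_factor: float = 2.0
    probation_zone: float = 0.2
    probation_period: int = 3
    stop_patience: int = 3
    max_unit_len: int | None = None
    max_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_memorize <= 1.0:
            raise ValueError("p_memorize must be in [0, 1]")
        if not 0.0 < self.promote_factor < 1.0:
            raise ValueError("promote_factor must be in (0, 1)")
        if self.demote_factor <= 1.0:
            raise ValueError("demote_factor must be > 1")
        if not 0.0 <= self.probation_zone <= 1.0:
            raise ValueError("probation_zone must be in [0, 1]")
        if self.max_unit_len is not None and self.max_unit_len < 1:
            raise ValueError("max_unit_len must be positive or None")


@dataclass
class UnitType:
    form: str
    probation_age: int = 0
    last_verdict: str = VERDICT_NONE

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("unit form must be non-empty")
        if self.form[0] == " ":
            raise ValueError("unit form must not begin with a space")


class Lexicon:
    """Ordered collection of unit types; rank 1 (front) = most unit-like."""

    def __init__(self, max_unit_len: int | None = None) -> None:
        self.entries: list[UnitType] = []
        self.max_unit_len = max_unit_len
        self._pos: dict[str, int] = {}
        self._max_form_len = 0

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, form: str) -> bool:
        return form in self._pos

    def __iter__(self):
        return iter(self.entries)

    def forms(self) -> list[str]:
        return [e.form for e in self.entries]

    def rank(self, form: str) -> int:
        """1-based rank of a form (front = 1)."""
        return self._pos[form] + 1

    def entry(self, form: str) -> UnitType:
        return self.entries[self._pos[form]]

    # -- mutation ------------------------------------------------------------
    def add(self, form: str) -> bool:
        """Append a new type at the end (lowest rank); no-op if present or
        longer than ``max_unit_len``.  Returns True if appended."""
        if form in self._pos:
            return False
        if self.max_unit_len is not None and effective_length(form) > self.max_unit_len:
            return False
        self._pos[form] = len(self.entries)
        self.entries.append(UnitType(form))
        self._max_form_len = max(self._max_form_len, len(form))
        return True

    def move(self, form: str, new_rank: int) -> None:
        """Move a form to a new 1-based rank, preserving the relative order
        of all other entries."""
        old = self._pos[form]
        new = min(max(new_rank, 1), len(self.entries)) - 1
        if new == old:
            return
        entry = self.entries.pop(old)
        self.entries.insert(new, entry)
        lo, hi = (new, old) if new < old else (old, new)
        for i in range(lo, hi + 1):
            self._pos[self.entries[i].form] = i

    def replace_entries(self, entries: list[UnitType]) -> None:
        self.entries = entries
        self._pos = {e.form: i for i, e in enumerate(entries)}
        self._max_form_len = max((len(e.form) for e in entries), default=0)

    def top_fraction(self, fraction: float) -> list[str]:
        k = math.ceil(fraction * len(self.entries))
        return [e.form for e in self.entries[:k]]

    @property
    def max_form_len(self) -> int:
        return self._max_form_len

    # -- persistence ---------------------------------------------------------
    def to_file(self, path: str | Path, config: LiBConfig | None = None) -> None:
        """One form per rank-ordered line, spaces rendered as ``␣``."""
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("# cogseg lexicon v1\n")
            if config is not None:
                fh.write(f"# config: {json.dumps(vars(config), sort_keys=True)}\n")
            for e in self.entries:
                fh.write(e.form.replace(" ", "␣") + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Lexicon":
        lex: Lexicon | None = None
        max_len: int | None = None
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# config: "):
                    cfg = json.loads(line[len("# config: "):])
                    max_len = cfg.get("max_unit_len")
                    continue
                if line.startswith("#") or not line:
                    continue
                if lex is None:
                    lex = cls(max_unit_len=max_len)
                lex.add(line.replace("␣", " "))
        if lex is None:
            lex = cls(max_unit_len=max_len)
        return lex


@dataclass
class EpochRecord:
    epoch: int
    encoding_bits: float
    lexicon_size: int
    batch_id: int


@dataclass
class TrainReport:
    records: list[EpochRecord] = field(default_factory=list)
    stop_reason: str = ""


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def match_candidates(lexicon: Lexicon, rendered: str, position: int) -> list[UnitType]:
    """All lexicon types whose form is a prefix of ``rendered`` at
    ``position``, longest first."""
    if rendered[position] == " ":
        raise ValueError(f"position {position} is on a space")
    out: list[UnitType] = []
    max_k = min(len(rendered) - position, lexicon.max_form_len)
    for k in range(max_k, 0, -1):
        form = rendered[position : position + k]
        if form in lexicon:
            out.append(lexicon.entry(form))
    return out


def _top_two(lexicon: Lexicon, rendered: str, position: int) -> list[str]:
    out: list[str] = []
    max_k = min(len(rendered) - position, lexicon.max_form_len)
    for k in range(max_k, 0, -1):
        form = rendered[position : position + k]
        if form in lexicon:
            out.append(form)
            if len(out) == 2:
                break
    return out


def _longest_match(lexicon: Lexicon, rendered: str, position: int) -> str | None:
    max_k = min(len(rendered) - position, lexicon.max_form_len)
    for k in range(max_k, 0, -1):
        form = rendered[position : position + k]
        if form in lexicon:
            return form
    return None


def _advance(rendered: str, position: int, form_len: int) -> int:
    """Token end after absorbing the boundary space that follows a unit
    ending at a word boundary."""
    end = position + form_len
    if end < len(rendered) and rendered[end] == " ":
        end += 1
    return end


def _greedy_boundaries(
    lexicon: Lexicon, rendered: str, start: int, first_form: str | None
) -> list[int]:
    """Token end offsets of a plain greedy larger-first segmentation from
    ``start`` to the end of ``rendered``, optionally forcing the first unit.
    Unknown symbols are emitted as singleton tokens."""
    bounds: list[int] = []
    pos = start
    form = first_form
    while pos < len(rendered):
        if form is None:
            form = _longest_match(lexicon, rendered, pos)
        if form is None:
            form = rendered[pos]
        pos = _advance(rendered, pos, len(form))
        bounds.append(pos)
        form = None
    return bounds


def lookahead_token_count(
    lexicon: Lexicon,
    rendered: str,
    start: int,
    first_unit: UnitType | str,
    horizon_end: int,
) -> int:
    """Tokens produced by taking ``first_unit`` then greedy larger-first
    segmentation (no nested counterfactuals) until ``horizon_end``."""
    form = first_unit.form if isinstance(first_unit, UnitType) else first_unit
    count = 0
    for bound in _greedy_boundaries(lexicon, rendered, start, form):
        count += 1
        if bound >= horizon_end:
            break
    return count


@dataclass
class Choice:
    """Outcome of one selection step."""

    token: UnitToken
    novel_symbol: str | None = None
    verdict: tuple[str, str] | None = None  # (largest-candidate form, good|bad)
    counts: tuple[int, int] | None = None  # (selected, rejected) lookahead counts


def choose_unit(
    lexicon: Lexicon, rendered: str, position: int, evaluate: bool = True
) -> Choice:
    """Select the unit token starting at ``position``.

    Larger-first: the longest matching type is the default.  With
    ``evaluate``, the largest candidate is checked counterfactually against
    the second largest over their shared lookahead horizon (the first
    character offset where both greedy continuations resynchronize): if it
    yields strictly more tokens it is marked Bad and the runner-up is
    selected, otherwise it is marked Good.  Out-of-lexicon symbols are
    emitted as singleton tokens.
    """
    cands = _top_two(lexicon, rendered, position)
    if not cands:
        sym = rendered[position]
        end = _advance(rendered, position, 1)
        return Choice(
            UnitToken(rendered[position:end], (position, end)), novel_symbol=sym
        )
    selected = cands[0]
    verdict = None
    counts = None
    if evaluate and len(cands) == 2:
        big, second = cands
        b_bounds = _greedy_boundaries(lexicon, rendered, position, big)
        s_bounds = _greedy_boundaries(lexicon, rendered, position, second)
        horizon = min(set(b_bounds) & set(s_bounds))
        n_big = sum(1 for b in b_bounds if b <= horizon)
        n_second = sum(1 for b in s_bounds if b <= horizon)
        if n_big > n_second:
            verdict = (big, VERDICT_BAD)
            selected = second
            counts = (n_second, n_big)
        else:
            verdict = (big, VERDICT_GOOD)
            counts = (n_big, n_second)
    end = _advance(rendered, position, len(selected))
    token = UnitToken(rendered[position:end], (position, end))
    return Choice(token, verdict=verdict, counts=counts)


def segment_sequence(
    lexicon: Lexicon, sequence: Sequence, evaluate: bool = True
) -> SegmentationResult:
    """Segment one sequence left to right into contiguous unit tokens.

    Concatenated token forms reproduce the rendered sequence exactly; spaces
    at word boundaries are absorbed into the preceding token.
    """
    rendered = sequence.rendered
    result = SegmentationResult(tokens=[])
    pos = 0
    while pos < len(rendered):
        choice = choose_unit(lexicon, rendered, pos, evaluate=evaluate)
        result.tokens.append(choice.token)
        if choice.novel_symbol is not None:
            result.novel_symbols.append(choice.novel_symbol)
        if choice.verdict is not None:
            result.verdicts.append(choice.verdict)
            result.choice_counts.append(choice.counts)
        pos = choice.token.span[1]
    return result


# ---------------------------------------------------------------------------
# Lexicon update
# ---------------------------------------------------------------------------


def memorize_pairs(
    result: SegmentationResult,
    lexicon: Lexicon,
    rng: np.random.Generator,
    config: LiBConfig,
) -> Lexicon:
    """Memorize novel symbols and randomly sampled adjacent token pairs.

    Out-of-lexicon symbols are always appended.  Each adjacent token pair
    within the sequence is concatenated and appended at the end of the
    lexicon with probability ``p_memorize``, unless already present or
    longer than ``max_unit_len``.
    """
    for sym in result.novel_symbols:
        lexicon.add(sym)
    tokens = result.tokens
    for a, b in zip(tokens, tokens[1:]):
        if rng.random() < config.p_memorize:
            lexicon.add(a.form + b.form)
    return lexicon


def apply_rerank(
    lexicon: Lexicon,
    verdicts: Iterable[tuple[str, str]],
    promote_factor: float = 0.5,
    demote_factor: float = 2.0,
) -> Lexicon:
    """Move Good forms forward and Bad forms backward by rank multipliers.

    A Good form at rank r moves to ``ceil(r * promote_factor)``; a Bad form
    to ``min(|L|, ceil(r * demote_factor))``.  A Good verdict cancels the
    form's probation.
    """
    for form, verdict in verdicts:
        if form not in lexicon:
            raise KeyError(f"verdict for unknown form {form!r}")
        r = lexicon.rank(form)
        entry = lexicon.entry(form)
        if verdict == VERDICT_GOOD:
            entry.last_verdict = VERDICT_GOOD
            entry.probation_age = 0
            lexicon.move(form, math.ceil(r * promote_factor))
        elif verdict == VERDICT_BAD:
            entry.last_verdict = VERDICT_BAD
            lexicon.move(form, min(len(lexicon), math.ceil(r * demote_factor)))
        else:
            raise ValueError(f"unknown verdict {verdict!r}")
    return lexicon


def apply_forgetting(lexicon: Lexicon, config: LiBConfig) -> Lexicon:
    """Age the probation zone and remove stale entries.

    Entries in the tail ``probation_zone`` fraction of the lexicon age by
    one epoch; an entry whose probation age reaches ``probation_period``
    without a Good verdict is removed.  Single-symbol types are never
    removed (the alphabet must remain segmentable).  An entry protected by
    an earlier Good verdict re-enters a fresh probation instead of being
    immune forever.
    """
    n = len(lexicon)
    if n == 0:
        return lexicon
    first_tail_rank = math.floor((1.0 - config.probation_zone) * n) + 1
    kept: list[UnitType] = []
    for i, entry in enumerate(lexicon.entries):
        if i + 1 >= first_tail_rank:
            entry.probation_age += 1
            if entry.probation_age >= config.probation_period:
                if entry.last_verdict != VERDICT_GOOD:
                    if len(entry.form) > 1:
                        continue  # forgotten
                else:
                    entry.probation_age = 0
                    entry.last_verdict = VERDICT_NONE
        kept.append(entry)
    lexicon.replace_entries(kept)
    return lexicon


def encoding_bits(results: TSequence[SegmentationResult]) -> float:
    """Shannon code length of a batch under empirical token frequencies."""
    freqs: dict[str, int] = {}
    total = 0
    for r in results:
        for t in r.tokens:
            freqs[t.form] = freqs.get(t.form, 0) + 1
            total += 1
    if total == 0:
        raise ValueError("empty batch")
    log2_total = math.log2(total)
    return sum(c * (log2_total - math.log2(c)) for c in freqs.values())


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def train(
    corpus: Corpus, config: LiBConfig, large_corpus_mode: bool = False
) -> tuple[Lexicon, TrainReport]:
    """Train a LiB lexicon on a corpus.

    Each epoch: sample a batch (with replacement in the default small-corpus
    mode; sequentially without replacement in large-corpus mode), segment it
    with counterfactual evaluation while memorizing online, then re-rank by
    the collected verdicts, apply forgetting, and record the batch's
    encoding bits.  Small-corpus training stops when the bits have not
    reached a new minimum for ``stop_patience`` consecutive epochs;
    large-corpus training stops when the material is exhausted.
    Deterministic under a fixed seed.
    """
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    ss = np.random.SeedSequence(config.seed)
    batch_ss, memo_ss = ss.spawn(2)
    batch_rng = np.random.default_rng(batch_ss)
    memo_rng = np.random.default_rng(memo_ss)

    lexicon = Lexicon(max_unit_len=config.max_unit_len)
    report = TrainReport()
    n = len(corpus.sequences)

    order: list[int] | None = None
    cursor = 0
    if large_corpus_mode:
        order = list(batch_rng.permutation(n))

    best_bits = math.inf
    stale = 0
    stop_reason = "max-epochs"
    for epoch in range(1, config.max_epochs + 1):
        if large_corpus_mode:
            if cursor >= n:
                stop_reason = "material-exhausted"
                break
            idx = order[cursor : cursor + config.batch_size]
            cursor += len(idx)
        else:
            idx = batch_rng.integers(0, n, size=min(config.batch_size, n)).tolist()

        batch_results: list[SegmentationResult] = []
        verdicts: list[tuple[str, str]] = []
        for i in idx:
            res = segment_sequence(lexicon, corpus.sequences[i], evaluate=True)
            memorize_pairs(res, lexicon, memo_rng, config)
            batch_results.append(res)
            verdicts.extend(res.verdicts)

        apply_rerank(lexicon, verdicts, config.promote_factor, config.demote_factor)
        apply_forgetting(lexicon, config)
        bits = encoding_bits(batch_results)
        report.records.append(EpochRecord(epoch, bits, len(lexicon), epoch))

        if not large_corpus_mode:
            if bits < best_bits - 1e-9:
                best_bits = bits
                stale = 0
            else:
                stale += 1
            if stale >= config.stop_patience:
                stop_reason = "no-improvement"
                break
    else:
        if large_corpus_mode and cursor >= n:
            stop_reason = "material-exhausted"

    report.stop_reason = stop_reason
    return lexicon, report


def segment_corpus(
    lexicon: Lexicon, corpus: Corpus, evaluate: bool = True
) -> list[SegmentationResult]:
    """Segment every sequence with a frozen lexicon (no learning)."""
    return [segment_sequence(lexicon, seq, evaluate=evaluate) for seq in corpus]
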