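"""The LiB learner: selection, counterfactual evaluation, lexicon update,
and training dynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cogseg import Corpus, LiBConfig, Sequence, segment_sequence, train
from cogseg.lib_model import (
    Lexicon,
    apply_forgetting,
    apply_rerank,
    choose_unit,
    encoding_bits,
    lookahead_token_count,
    match_candidates,
    memorize_pairs,
    segment_corpus,
)

from conftest import make_lexicon


# ---------------------------------------------------------------------------
# candidate matching and lookahead
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "forms,rendered,pos,expected",
    [
        (["ab", "a", "b"], "ab ", 0, ["ab", "a"]),
        (["a"], "z ", 0, []),
        (["to do ", "to ", "do "], "to do ", 0, ["to do ", "to "]),
    ],
)
def test_match_candidates_longest_first(forms, rendered, pos, expected):
    lex = make_lexicon(forms)
    assert [u.form for u in match_candidates(lex, rendered, pos)] == expected


def test_match_candidates_rejects_space_position():
    lex = make_lexicon(["a"])
    with pytest.raises(ValueError):
        match_candidates(lex, "a b ", 1)


@pytest.mark.parametrize(
    "first,expected",
    [("ab", 2), ("a", 3)],
)
def test_lookahead_counts_to_horizon(first, expected):
    lex = make_lexicon(["ab", "a", "b"])
    assert lookahead_token_count(lex, "aba ", 0, first, 4) == expected


def test_lookahead_single_unit_spanning_horizon():
    lex = make_lexicon(["abc"])
    assert lookahead_token_count(lex, "abc ", 0, "abc", 3) == 1


# ---------------------------------------------------------------------------
# counterfactual selection
# ---------------------------------------------------------------------------


def test_largest_wins_when_it_saves_tokens():
    lex = make_lexicon(["ab", "a", "b"])
    choice = choose_unit(lex, "aba ", 0)
    assert choice.token.form == "ab"
    assert choice.verdict == ("ab", "good")


def test_nonmatching_larger_form_is_ignored():
    lex = make_lexicon(["abc", "ab", "c", "a", "b"])
    choice = choose_unit(lex, "abab ", 0)
    assert choice.token.form == "ab"
    assert choice.verdict == ("ab", "good")


def test_tie_on_lookahead_keeps_largest():
    lex = make_lexicon(["ab", "a", "bc", "b", "c"])
    choice = choose_unit(lex, "abc ", 0)
    assert choice.token.form == "ab"
    assert choice.verdict == ("ab", "good")
    assert choice.counts[0] == choice.counts[1]


def test_harmful_largest_is_marked_bad_and_runner_up_selected():
    # choosing "ab" strands "c" + "d"; choosing "a" lets "bcd" cover the rest
    lex = make_lexicon(["ab", "bcd ", "a", "b", "c", "d"])
    choice = choose_unit(lex, "abcd ", 0)
    assert choice.verdict == ("ab", "bad")
    assert choice.token.form == "a"
    assert choice.counts[0] <= choice.counts[1]


def test_unknown_symbol_becomes_singleton_token():
    lex = make_lexicon(["a"])
    choice = choose_unit(lex, "z ", 0)
    assert choice.token.form == "z "  # owns the boundary space
    assert choice.novel_symbol == "z"


# ---------------------------------------------------------------------------
# sequence segmentation
# ---------------------------------------------------------------------------


def test_empty_lexicon_emits_novel_symbols():
    seq = Sequence.from_texts(["ab"], seq_id="s0")
    res = segment_sequence(Lexicon(), seq)
    assert res.novel_symbols == ["a", "b"]
    assert res.token_count == 2
    assert res.concatenated() == "ab "


def test_word_by_word_fallback(tiny_sequence):
    lex = make_lexicon([w.text + " " for w in tiny_sequence.words])
    res = segment_sequence(lex, tiny_sequence)
    assert res.token_count == len(tiny_sequence.words)


def test_larger_first_segments_into_collocations():
    lex = make_lexicon(
        ["i was ", "i ", "was ", "trying to ", "trying ", "to ", "do ", "what "]
    )
    seq = Sequence.from_texts(["i", "was", "trying", "to", "do"], seq_id="s0")
    res = segment_sequence(lex, seq)
    assert [t.form for t in res.tokens] == ["i was ", "trying to ", "do "]
    assert res.token_count == 3


@given(
    st.lists(
        st.text(alphabet="abc", min_size=1, max_size=4), min_size=1, max_size=6
    ),
    st.sets(st.text(alphabet="abc ", min_size=1, max_size=5), max_size=12),
)
def test_coverage_is_exact_for_any_lexicon(texts, forms):
    seq = Sequence.from_texts(texts, seq_id="s0")
    lex = make_lexicon(f for f in forms if f.strip() and not f.startswith(" "))
    for evaluate in (False, True):
        res = segment_sequence(lex, seq, evaluate=evaluate)
        assert res.concatenated() == seq.rendered


@given(
    st.lists(
        st.text(alphabet="ab", min_size=1, max_size=4), min_size=1, max_size=6
    ),
    st.sets(st.text(alphabet="ab ", min_size=1, max_size=5), max_size=12),
)
def test_greedy_selection_matches_longest_prefix_oracle(texts, forms):
    """With evaluation off, each token is the longest matching prefix found
    by a brute-force scan over the whole lexicon."""
    seq = Sequence.from_texts(texts, seq_id="s0")
    lex = make_lexicon(f for f in forms if f.strip() and not f.startswith(" "))
    res = segment_sequence(lex, seq, evaluate=False)
    rendered = seq.rendered
    pos = 0
    for token in res.tokens:
        best = max(
            (f for f in lex.forms() if rendered.startswith(f, pos)),
            key=len,
            default=rendered[pos],
        )
        end = pos + len(best)
        if end < len(rendered) and rendered[end] == " ":
            end += 1
        assert token.form == rendered[pos:end]
        pos = end


@given(
    st.lists(
        st.text(alphabet="ab", min_size=1, max_size=4), min_size=1, max_size=6
    ),
    st.sets(st.text(alphabet="ab ", min_size=1, max_size=5), max_size=12),
)
def test_counterfactual_never_picks_worse_candidate(texts, forms):
    seq = Sequence.from_texts(texts, seq_id="s0")
    lex = make_lexicon(f for f in forms if f.strip() and not f.startswith(" "))
    res = segment_sequence(lex, seq, evaluate=True)
    for selected, rejected in res.choice_counts:
        assert selected <= rejected


def test_adding_a_correct_multiword_type_never_adds_tokens():
    words = ["up", "my", "mind", "what", "to", "do"]
    seq = Sequence.from_texts(words, seq_id="s0")
    base = make_lexicon([w + " " for w in words])
    n_before = segment_sequence(base, seq).token_count
    richer = make_lexicon([w + " " for w in words] + ["my mind "])
    n_after = segment_sequence(richer, seq).token_count
    assert n_after <= n_before
    assert n_after == n_before - 1


# ---------------------------------------------------------------------------
# lexicon update mechanisms
# ---------------------------------------------------------------------------


def test_memorized_pair_is_appended_at_end():
    seq = Sequence.from_texts(["i", "have"], seq_id="s0")
    lex = make_lexicon(["i ", "have "])
    res = segment_sequence(lex, seq)
    rng = np.random.default_rng(0)  # first draw < 1.0 → pair sampled
    memorize_pairs(res, lex, rng, LiBConfig(p_memorize=1.0))
    assert lex.forms()[-1] == "i have "


def test_memorize_respects_uniqueness_and_length_cap():
    seq = Sequence.from_texts(["abc", "def"], seq_id="s0")
    lex = make_lexicon(["abc ", "def ", "abc def "])
    res = segment_sequence(lex, seq, evaluate=False)
    size = len(lex)
    memorize_pairs(res, lex, np.random.default_rng(0), LiBConfig(p_memorize=1.0))
    assert len(lex) == size  # duplicate not re-added

    capped = make_lexicon(["abc ", "def "], max_unit_len=4)
    res = segment_sequence(capped, seq, evaluate=False)
    memorize_pairs(res, capped, np.random.default_rng(0), LiBConfig(p_memorize=1.0, max_unit_len=4))
    assert "abc def " not in capped


@pytest.mark.parametrize(
    "rank,verdict,expected",
    [(8, "good", 4), (1, "good", 1), (3, "bad", 5)],
)
def test_rerank_moves(rank, verdict, expected):
    lex = make_lexicon([f"u{i} " for i in range(1, 9)][: 8 if rank == 8 else 5])
    form = lex.forms()[rank - 1]
    apply_rerank(lex, [(form, verdict)], promote_factor=0.5, demote_factor=2.0)
    assert lex.rank(form) == expected


def test_rerank_preserves_relative_order_of_others():
    lex = make_lexicon(["a ", "b ", "c ", "d ", "e "])
    apply_rerank(lex, [("d ", "good")])  # rank 4 -> 2
    assert lex.forms() == ["a ", "d ", "b ", "c ", "e "]


def test_rerank_unknown_form_is_a_contract_violation():
    lex = make_lexicon(["a "])
    with pytest.raises(KeyError):
        apply_rerank(lex, [("zz ", "good")])


def test_forgetting_removes_stale_tail_entries():
    cfg = LiBConfig(probation_zone=0.5, probation_period=2)
    lex = make_lexicon(["aa ", "bb ", "cc ", "dd "])
    for _ in range(2):
        apply_forgetting(lex, cfg)
    assert lex.forms() == ["aa ", "bb "]


def test_good_verdict_cancels_probation():
    cfg = LiBConfig(probation_zone=1.0, probation_period=2)
    lex = make_lexicon(["aa ", "bb "])
    apply_forgetting(lex, cfg)  # both age to 1
    apply_rerank(lex, [("bb ", "good")])  # probation cancelled
    apply_forgetting(lex, cfg)
    assert "bb " in lex
    assert "aa " not in lex


def test_single_symbols_are_never_forgotten():
    cfg = LiBConfig(probation_zone=1.0, probation_period=1)
    lex = make_lexicon(["a", "b", "cd "])
    apply_forgetting(lex, cfg)
    assert lex.forms() == ["a", "b"]


def test_front_entries_do_not_age():
    cfg = LiBConfig(probation_zone=0.2, probation_period=2)
    lex = make_lexicon([f"u{i} " for i in range(10)])
    apply_forgetting(lex, cfg)
    assert lex.entry("u0 ").probation_age == 0
    assert lex.entry("u9 ").probation_age == 1


@pytest.mark.parametrize(
    "forms,expected",
    [
        (["a", "a", "b", "b"], 4.0),
        (["a", "a", "a"], 0.0),
        (["a", "b", "c", "d"], 8.0),
    ],
)
def test_encoding_bits(forms, expected):
    from cogseg.core import SegmentationResult, UnitToken

    res = SegmentationResult(
        tokens=[UnitToken(f, (0, len(f))) for f in forms]
    )
    assert encoding_bits([res]) == pytest.approx(expected)


def test_encoding_bits_rejects_empty_batch():
    with pytest.raises(ValueError):
        encoding_bits([])


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _repeat_corpus():
    seqs = [
        Sequence.from_texts(["ab"] * 4, seq_id=f"s{i}") for i in range(50)
    ]
    return Corpus(seqs, source_id="abab")


def test_training_learns_repeated_chunk_above_symbols():
    corpus = _repeat_corpus()
    cfg = LiBConfig(batch_size=20, seed=3, max_epochs=40)
    lex, report = train(corpus, cfg)
    multi = [f for f in lex.forms() if len(f) > 1]
    assert multi, "no composite units learned"
    best = min(lex.rank(f) for f in multi)
    assert best < min(lex.rank("a"), lex.rank("b"))
    assert report.stop_reason in ("no-improvement", "max-epochs")


def test_training_is_deterministic_under_seed():
    corpus = _repeat_corpus()
    cfg = LiBConfig(batch_size=20, seed=7, max_epochs=30)
    lex1, rep1 = train(corpus, cfg)
    lex2, rep2 = train(corpus, cfg)
    assert lex1.forms() == lex2.forms()
    assert [r.encoding_bits for r in rep1.records] == [
        r.encoding_bits for r in rep2.records
    ]


def test_stop_rule_fires_patience_epochs_after_last_minimum():
    corpus = _repeat_corpus()
    cfg = LiBConfig(batch_size=20, seed=5, stop_patience=3, max_epochs=100)
    _, report = train(corpus, cfg)
    assert report.stop_reason == "no-improvement"
    bits = [r.encoding_bits for r in report.records]
    best_epoch = int(np.argmin(bits)) + 1
    assert report.records[-1].epoch == best_epoch + cfg.stop_patience


def test_large_corpus_mode_consumes_material_once():
    corpus = _repeat_corpus()
    cfg = LiBConfig(batch_size=20, seed=1, max_epochs=100)
    _, report = train(corpus, cfg, large_corpus_mode=True)
    assert report.stop_reason == "material-exhausted"
    assert len(report.records) == math.ceil(len(corpus) / cfg.batch_size)


def test_alphabet_and_uniqueness_hold_after_training():
    corpus = _repeat_corpus()
    lex, _ = train(corpus, LiBConfig(batch_size=20, seed=2, max_epochs=20))
    forms = lex.forms()
    assert len(forms) == len(set(forms))
    assert {"a", "b"} <= set(forms)
    segs = segment_corpus(lex, corpus)
    for seg, seq in zip(segs, corpus):
        assert seg.concatenated() == seq.rendered


def test_lexicon_file_roundtrip(tmp_path):
    lex = make_lexicon(["i was ", "i ", "a"])
    p = tmp_path / "lex.txt"
    lex.to_file(p, config=LiBConfig(max_unit_len=9))
    back = Lexicon.from_file(p)
    assert back.forms() == lex.forms()
    assert back.max_unit_len == 9
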