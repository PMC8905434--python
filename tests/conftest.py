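import hypothesis
import pytest

from cogseg import Corpus, FixationTable, Sequence
from cogseg.lib_model import Lexicon

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None
)
hypothesis.settings.load_profile("ci")


def make_table(rows):
    """Build a FixationTable from (seq_id, idx, word, count) rows."""
    t = FixationTable()
    for seq_id, idx, word, count in rows:
        t.set(seq_id, idx, word, count)
    return t


def table_from_counts(counts, seq_id="s0"):
    """FixationTable with one synthetic word per count value."""
    t = FixationTable()
    for i, c in enumerate(counts):
        t.set(seq_id, i, f"w{i}", c)
    return t


def make_lexicon(forms, max_unit_len=None):
    lex = Lexicon(max_unit_len=max_unit_len)
    for f in forms:
        lex.add(f)
    return lex


@pytest.fixture
def tiny_sequence():
    return Sequence.from_texts(["i", "was", "trying", "to", "do"], seq_id="s0")


@pytest.fixture
def tiny_corpus(tiny_sequence):
    return Corpus([tiny_sequence], source_id="tiny")
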