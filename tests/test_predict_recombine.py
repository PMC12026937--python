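import sys

import numpy as np
import pytest

from rnadivide.partition import Fragment, make_fragments
from rnadivide.predict_recombine import (
    ExternalCommandPredictor,
    OraclePredictor,
    dividefold_predict,
    ideal_cutter,
    null_predictor,
    predict_fragments,
    recombine,
)
from rnadivide.pseudoknot import crossing
from rnadivide.structure_io import read_dotbracket


def from_dbn(seq, struct):
    return read_dotbracket(f">x\n{seq}\n{struct}\n")[0]


def test_oracle_predictor_whole_stem():
    ref = from_dbn("GGGAAACCCAAAGGGAAACCC", "(((...)))...(((...)))")
    frag = Fragment(((0, 10),))
    pairs = OraclePredictor(ref)(frag.extract(ref.sequence), frag)
    assert pairs == frozenset({(0, 8), (1, 7), (2, 6)})


def test_oracle_on_merged_fragment_recovers_outer_stem():
    struct = "(((....(((...)))....(((...)))....)))"
    seq = "GGG" + "A" * 4 + "GGGAAACCC" + "A" * 4 + "GGGAAACCC" + "A" * 4 + "CCC"
    ref = from_dbn(seq, struct)
    frag = Fragment(((0, 5), (31, 36)))  # both arms of the enclosing stem
    local = OraclePredictor(ref)(frag.extract(ref.sequence), frag)
    back = {(frag.local_to_global(i), frag.local_to_global(j)) for i, j in local}
    assert {(0, 35), (1, 34), (2, 33)} <= back


def test_recombine_offset_and_interval_map():
    assert recombine([{(0, 6)}], [Fragment(((5, 12),))]) == frozenset({(5, 11)})
    assert recombine([{(2, 10)}], [Fragment(((0, 5), (12, 20)))]) == frozenset(
        {(2, 17)}
    )
    assert recombine([], []) == frozenset()


def test_recombine_rejects_out_of_range():
    with pytest.raises(IndexError):
        recombine([{(0, 9)}], [Fragment(((0, 5),))])


def test_predict_fragments_failure_yields_empty(caplog):
    def broken(seq, frag):
        raise RuntimeError("boom")

    frags = make_fragments(20, [10])
    out = predict_fragments(frags, "A" * 20, broken)
    assert out == [frozenset(), frozenset()]


def test_short_sequence_goes_to_predictor_whole(synth_suite):
    s = synth_suite[0]
    pred, res = dividefold_predict(
        s, ideal_cutter(s), OraclePredictor(s), max_len=len(s) + 10
    )
    assert len(res.fragments) == 1
    assert pred.pairs == s.pairs


def test_oracle_end_to_end_recall_and_pseudoknot_semantics(synth_suite):
    """With ideal cuts and the oracle predictor every non-pseudoknot pair
    is recovered; missing pairs are exactly cross-fragment pairs (which
    are always pseudoknot pairs)."""
    for s in synth_suite[:60]:
        pred, res = dividefold_predict(
            s, ideal_cutter(s), OraclePredictor(s), max_len=300
        )
        assert pred.pairs <= s.pairs  # oracle cannot invent pairs
        missing = s.pairs - pred.pairs
        frag_of = {}
        for k, f in enumerate(res.fragments):
            for a, b in f.intervals:
                for p in range(a, b):
                    frag_of[p] = k
        cross_fragment = {
            (i, j) for i, j in s.pairs if frag_of[i] != frag_of[j]
        }
        assert missing == cross_fragment
        for p in missing:
            assert any(crossing(p, q) for q in s.pairs if q != p)


def test_null_predictor(synth_suite):
    s = synth_suite[1]
    pred, _ = dividefold_predict(s, ideal_cutter(s), null_predictor, max_len=300)
    assert pred.pairs == frozenset()


def test_external_command_predictor(tmp_path):
    """Shell adapter: FASTA in, dot-bracket on stdout (with an energy
    suffix, as folding tools print)."""
    script = tmp_path / "fold.py"
    script.write_text(
        "import sys\n"
        "seq = open(sys.argv[1]).read().splitlines()[1]\n"
        "print(seq)\n"
        "print('(' * 3 + '.' * (len(seq) - 6) + ')' * 3 + ' (-1.20)')\n"
    )
    pred = ExternalCommandPredictor(f"{sys.executable} {script} {{fasta}}")
    frag = Fragment(((0, 12),))
    pairs = pred("GGGAAAAAACCC", frag)
    assert pairs == frozenset({(0, 11), (1, 10), (2, 9)})


def test_external_command_predictor_failure():
    pred = ExternalCommandPredictor("false")
    with pytest.raises(RuntimeError):
        pred("ACGU", Fragment(((0, 4),)))
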