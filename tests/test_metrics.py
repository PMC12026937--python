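import numpy as np
import pytest

from rnadivide.labelgen import ideal_cut_points
from rnadivide.metrics import (
    bp_scores,
    break_rate,
    compression_rate,
    evaluate_pair,
    pk_scores,
)
from rnadivide.partition import Fragment, make_fragments
from rnadivide.structure_io import read_dotbracket


def frags(*intervals_lists):
    return [Fragment(tuple(iv)) for iv in intervals_lists]


def test_bp_scores_examples():
    truth = {(0, 8), (1, 7), (2, 6)}
    p = bp_scores(truth, truth)
    assert (p.precision, p.recall, p.fscore) == (1.0, 1.0, 1.0)
    p = bp_scores({(0, 8), (1, 7), (3, 5)}, truth)
    assert p.precision == pytest.approx(2 / 3)
    assert p.recall == pytest.approx(2 / 3)
    assert p.fscore == pytest.approx(2 / 3)
    p = bp_scores(set(), truth)
    assert (p.precision, p.recall, p.fscore) == (0.0, 0.0, 0.0)
    assert p.degenerate


def test_bp_scores_against_brute_force(rng):
    for _ in range(200):
        pool = [(int(i), int(i + d)) for i, d in
                zip(rng.integers(0, 40, 12), rng.integers(1, 20, 12))]
        pred = {p for p in pool if rng.random() < 0.5}
        truth = {p for p in pool if rng.random() < 0.5}
        # brute-force confusion counts over the union universe
        tp = sum(1 for p in pred if p in truth)
        fp = sum(1 for p in pred if p not in truth)
        fn = sum(1 for p in truth if p not in pred)
        s = bp_scores(pred, truth)
        assert (s.tp, s.fp, s.fn) == (tp, fp, fn)


def test_pk_scores_similarity_rule():
    truth = {(1, 10), (2, 9), (5, 15), (6, 14)}
    pred = {(1, 10), (6, 14)}  # one shared pair in each group
    s = pk_scores(pred, truth)
    assert (s.tp, s.fp, s.fn) == (1, 0, 0)
    assert s.fscore == 1.0


def test_pk_scores_requires_both_groups():
    truth = {(1, 10), (2, 9), (5, 15), (6, 14)}
    # shares a first-group pair, but its second group is elsewhere
    pred = {(1, 10), (7, 12)}
    s = pk_scores(pred, truth)
    assert (s.tp, s.fp, s.fn) == (0, 1, 1)


def test_pk_scores_no_pseudoknots_flagged():
    s = pk_scores({(0, 8)}, {(0, 8)})
    assert (s.precision, s.recall, s.fscore) == (0.0, 0.0, 0.0)
    assert s.degenerate


def test_pk_scores_identity(synth_suite):
    from rnadivide.pseudoknot import enumerate_pseudoknots

    for s in synth_suite[:40]:
        if enumerate_pseudoknots(s.pairs):
            m = pk_scores(s.pairs, s.pairs)
            assert (m.precision, m.recall, m.fscore) == (1.0, 1.0, 1.0)


def test_compression_rate_examples():
    assert compression_rate(frags([(0, 100)]), 100) == 0.0
    assert compression_rate(frags([(0, 50)], [(50, 100)]), 100) == pytest.approx(0.5)
    assert compression_rate(frags([(0, 60)], [(60, 100)]), 100) == pytest.approx(0.48)


def test_compression_rate_bounds_and_maximum(rng):
    for _ in range(100):
        n = int(rng.integers(20, 400))
        k = int(rng.integers(1, 8))
        cuts = sorted(rng.choice(np.arange(1, n), size=min(k, n - 1), replace=False).tolist())
        fr = make_fragments(n, cuts)
        c = compression_rate(fr, n)
        p = len(fr)
        assert 0.0 <= c <= 1.0 - 1.0 / p + 1e-12
    # equal fragments maximize compression
    equal = compression_rate(frags([(0, 25)], [(25, 50)], [(50, 75)], [(75, 100)]), 100)
    skew = compression_rate(frags([(0, 70)], [(70, 80)], [(80, 90)], [(90, 100)]), 100)
    assert equal > skew


def test_compression_rate_rejects_bad_cover():
    with pytest.raises(ValueError):
        compression_rate(frags([(0, 50)]), 100)


def test_break_rate_examples():
    s = read_dotbracket(">x\nGGGAAACCC\n(((...)))\n")[0]
    assert break_rate(s, frags([(0, 4)], [(4, 9)])) == 1.0
    assert break_rate(s, frags([(0, 9)])) == 0.0


def test_break_rate_excludes_pseudoknots():
    # crossing helix is removed before counting: only the kept group counts
    s = read_dotbracket(">x\nGGAAGGAACCAACC\n((..[[..))..]]\n")[0]
    # IR keeps {(0,9),(1,8)}; cutting at 4 breaks both kept pairs
    assert break_rate(s, frags([(0, 4)], [(4, 14)])) == 1.0


def test_break_rate_zero_for_ideal_labels(synth_suite):
    for s in synth_suite:
        cuts = ideal_cut_points(s)
        if cuts:
            assert break_rate(s, make_fragments(len(s), cuts)) == 0.0


def test_evaluate_pair_report(synth_suite):
    s = synth_suite[0]
    rep = evaluate_pair(s, s)
    assert rep["bp"]["fscore"] == 1.0
    assert rep["n"] == len(s)
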