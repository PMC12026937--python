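import numpy as np
import pytest

from rnadivide.partition import (
    Fragment,
    NotDivisibleError,
    PeakParams,
    make_fragments,
    recursive_partition,
    select_cut_points,
    uniform_random_cuts,
)


def test_fragment_mapping_and_slicing():
    f = Fragment(((0, 5), (12, 20)))
    assert f.total_length == 13
    assert f.local_to_global(0) == 0
    assert f.local_to_global(5) == 12
    assert f.local_to_global(10) == 17
    assert f.global_to_local(17) == 10
    assert f.extract("ABCDEFGHIJKLMNOPQRST") == "ABCDE" + "MNOPQRST"
    assert f.slice_local(3, 8).intervals == ((3, 5), (12, 15))
    with pytest.raises(IndexError):
        f.local_to_global(13)
    with pytest.raises(ValueError):
        Fragment(((0, 5), (3, 8)))  # overlap
    # adjacent intervals merge
    assert Fragment(((0, 5), (5, 9))).intervals == ((0, 9),)


def test_induced_pairs_local_coordinates():
    f = Fragment(((0, 5), (12, 20)))
    pairs = {(2, 17), (1, 7), (13, 19)}
    assert f.induced_pairs(pairs) == frozenset({(2, 10), (6, 12)})


def test_select_cut_points_peaks():
    scores = [0.1, 0.1, 0.9, 0.1, 0.1, 0.8] + [0.1] * 10
    cuts = select_cut_points(scores, PeakParams(height=0.28, distance=2, margin=1))
    assert cuts == (2, 5)


def test_select_cut_points_plateau_takes_first_index():
    scores = [0.0] * 30
    scores[10] = scores[11] = scores[12] = 0.9
    cuts = select_cut_points(scores, PeakParams(height=0.5, distance=3, margin=2))
    assert 10 in cuts


def test_select_cut_points_fallback_forces_two():
    cuts = select_cut_points(np.full(400, 0.5), PeakParams())
    assert len(cuts) == 2
    assert cuts[1] - cuts[0] >= PeakParams().distance


def test_select_cut_points_not_divisible():
    with pytest.raises(NotDivisibleError):
        select_cut_points([0.5, 0.5, 0.5], PeakParams())
    with pytest.raises(NotDivisibleError):
        select_cut_points(np.full(30, 0.5), PeakParams())  # margins leave no room


def test_select_cut_points_contract_on_random_vectors(rng):
    """Always >= 2 interior cuts, or the documented error."""
    params = PeakParams()
    for _ in range(1000):
        n = int(rng.integers(4, 1500))
        scores = rng.random(n)
        try:
            cuts = select_cut_points(scores, params)
        except NotDivisibleError:
            continue
        assert len(cuts) >= 2
        assert all(0 < c < n for c in cuts)
        assert list(cuts) == sorted(set(cuts))


def test_make_fragments_two_parts_no_merge():
    frags = make_fragments(10, [4])
    assert [f.intervals for f in frags] == [((0, 4),), ((4, 10),)]


def test_make_fragments_outer_merge():
    frags = make_fragments(20, [5, 12])
    assert [f.intervals for f in frags] == [((0, 5), (12, 20)), ((5, 12),)]
    # five parts -> four fragments, outer merged
    frags = make_fragments(20, [5, 9, 12, 16])
    assert len(frags) == 4
    assert frags[0].intervals == ((0, 5), (16, 20))


def test_make_fragments_exact_cover_property(rng):
    for _ in range(1000):
        n = int(rng.integers(4, 500))
        k = int(rng.integers(1, min(6, n - 1)))
        cuts = sorted(rng.choice(np.arange(1, n), size=k, replace=False).tolist())
        frags = make_fragments(n, cuts)
        covered = sorted(iv for f in frags for iv in f.intervals)
        pos = 0
        for a, b in covered:
            assert a == pos
            pos = b
        assert pos == n


def test_make_fragments_validates_cuts():
    with pytest.raises(ValueError):
        make_fragments(10, [])
    with pytest.raises(ValueError):
        make_fragments(10, [0])
    with pytest.raises(ValueError):
        make_fragments(10, [4, 4])


def center_cutter(sub_seq, frag=None):
    n = len(sub_seq)
    if n < 8:
        raise NotDivisibleError("too short")
    return (n // 3, 2 * n // 3)


def test_recursive_partition_short_sequence_single_fragment():
    res = recursive_partition("A" * 800, center_cutter, max_len=1000)
    assert [f.intervals for f in res.fragments] == [((0, 800),)]


def test_recursive_partition_cover_and_progress(rng):
    for _ in range(50):
        n = int(rng.integers(150, 3000))
        res = recursive_partition("A" * n, center_cutter, max_len=140)
        res.validate()
        assert all(
            f.total_length <= 140 or f in res.oversized for f in res.fragments
        )
        assert res.max_depth <= int(np.ceil(np.log2(n / 140))) + 6


def test_recursive_partition_traces_one_iteration():
    cuts_map = {2400: (700, 1600)}

    def cutter(sub, frag=None):
        if len(sub) in cuts_map:
            return cuts_map[len(sub)]
        raise NotDivisibleError("stop")

    res = recursive_partition("A" * 2400, cutter, max_len=1000)
    intervals = sorted(f.intervals for f in res.fragments)
    assert ((700, 1600),) in intervals
    # the merged outer fragment could not be re-cut and is flagged
    assert ((0, 700), (1600, 2400)) in intervals
    assert len(res.oversized) == 1


def test_recursive_partition_enforces_floor():
    with pytest.raises(ValueError):
        recursive_partition("A" * 500, center_cutter, max_len=50)


def test_uniform_random_cuts_contract(rng):
    params = PeakParams()
    for _ in range(200):
        n = int(rng.integers(300, 2000))
        k = int(rng.integers(2, 6))
        cuts = uniform_random_cuts(n, k, rng, params)
        assert len(cuts) >= 2
        assert all(params.margin <= c <= n - params.margin for c in cuts)
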