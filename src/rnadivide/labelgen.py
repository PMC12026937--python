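"""Ideal cut-point training labels.

Labels mark boundaries between minimally nested stems: cutting there
breaks no base pair of the pseudoknot-free structure once the outer
merge is taken into account.  Pseudoknots are removed first (IR
criterion).  Helices that enclose the entire remaining structure are
peeled — cuts placed inside them are safe because the outer merge keeps
both arms of an enclosing stem in the same fragment — and one cut is
emitted at the midpoint of each maximal run of safe boundaries
separating consecutive top-level blocks (the peeled 5' arm, the
top-level paired intervals, the peeled 3' arm).

Each partition iteration of a long structure contributes one training
example, so label generation doubles as data augmentation; base-pair
mutation provides a second augmentation, resampling the letters of a
random fraction of pairs as fresh canonical pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .partition import make_fragments
from .pseudoknot import remove_pseudoknots_ir
from .structure_io import RnaRecord, StructureRecord, as_pairset

__all__ = [
    "TrainingExample",
    "ideal_cut_points",
    "ideal_cut_points_from_pairs",
    "recursive_training_examples",
    "mutate_base_pairs",
    "CANONICAL_PAIRS",
]

CANONICAL_PAIRS = (("A", "U"), ("G", "C"), ("G", "U"))


@dataclass(frozen=True)
class TrainingExample:
    """A (possibly concatenated) sequence with target cut points.

    ``pairs`` holds the structure induced on the sequence (local
    coordinates) so augmentation can re-mutate letters each epoch;
    ``origin_id``/``depth`` record provenance.
    """

    sequence: str
    cuts: tuple
    pairs: frozenset
    origin_id: str
    depth: int

    def __post_init__(self):
        n = len(self.sequence)
        if not all(0 < c < n for c in self.cuts):
            raise ValueError(f"cuts {self.cuts} not interior to n={n}")
        object.__setattr__(self, "cuts", tuple(sorted(self.cuts)))
        object.__setattr__(self, "pairs", as_pairset(self.pairs, n))


def _top_level(pairs: set) -> list[tuple]:
    """Pairs not nested inside any other pair, sorted (disjoint spans)."""
    return sorted(
        p for p in pairs
        if not any(q[0] < p[0] and p[1] < q[1] for q in pairs if q != p)
    )


def ideal_cut_points_from_pairs(n: int, pairs) -> tuple:
    """Ideal cut points for a length-n sequence with the given pairs.

    Returns a sorted tuple of cut indices; empty when the structure is
    not divisible without breaking a pair (single top-level stem with no
    room around it, or no structure at all).
    """
    work = set(remove_pseudoknots_ir(pairs))
    peeled: list[tuple] = []
    while work:
        top = _top_level(work)
        if len(top) >= 2:
            break
        peeled.append(top[0])
        work.remove(top[0])
    if not work:
        return ()
    top = _top_level(work)
    blocks = [(i, j) for i, j in top]
    if peeled:
        arm5 = (min(p[0] for p in peeled), max(p[0] for p in peeled))
        arm3 = (min(p[1] for p in peeled), max(p[1] for p in peeled))
        blocks = [arm5] + blocks + [arm3]

    def safe(b: int) -> bool:
        return not any(i < b <= j for i, j in work)

    cuts = []
    missing_arm_cut = False
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        run = [b for b in range(e1 + 1, s2 + 1) if 0 < b < n and safe(b)]
        if not run:
            if peeled and ((s1, e1) == blocks[0] or (s2, e2) == blocks[-1]):
                missing_arm_cut = True
            continue
        cuts.append((run[0] + run[-1]) // 2)
    if peeled and (missing_arm_cut or len(cuts) < 2):
        # Enclosing stem cannot be protected by the outer merge: an arm
        # gap is absent or fewer than three parts would be produced.
        return ()
    return tuple(sorted(cuts))


def ideal_cut_points(s: StructureRecord) -> tuple:
    """Ideal cut points of a structure record (pseudoknots removed by the
    IR criterion first); cutting at any returned boundary breaks zero
    non-pseudoknot pairs once fragments are built with the outer merge."""
    return ideal_cut_points_from_pairs(len(s), s.pairs)


def recursive_training_examples(
    s: StructureRecord, max_len: int = 1000
) -> list[TrainingExample]:
    """Expand one structure into training examples across partition
    iterations.

    The full record contributes an example when it has ideal cuts; its
    fragments (built with the outer merge, structures re-induced in
    fragment-local coordinates) recurse while longer than ``max_len``.
    Fragments with no divisible structure are silently dropped.
    """
    out: list[TrainingExample] = []

    def rec(seq: str, pairs: frozenset, depth: int):
        cuts = ideal_cut_points_from_pairs(len(seq), pairs)
        if not cuts:
            return
        out.append(TrainingExample(seq, cuts, pairs, s.id, depth))
        for frag in make_fragments(len(seq), cuts):
            if frag.total_length > max_len:
                rec(frag.extract(seq), frag.induced_pairs(pairs), depth + 1)

    rec(s.sequence, s.pairs, 0)
    return out


def mutate_sequence_pairs(
    sequence: str,
    pairs,
    rng: np.random.Generator,
    max_fraction: float = 0.10,
) -> str:
    """Return the sequence with a random fraction f ~ U(0, max_fraction)
    of base pairs resampled as fresh canonical pairs (AU, GC or GU, in
    random order); pair topology and unpaired positions are untouched."""
    if not 0.0 <= max_fraction <= 1.0:
        raise ValueError("max_fraction must be in [0, 1]")
    pair_list = sorted(pairs)
    if not pair_list or max_fraction == 0.0:
        return sequence
    f = rng.uniform(0.0, max_fraction)
    k = int(round(f * len(pair_list)))
    if k == 0:
        return sequence
    chosen = rng.choice(len(pair_list), size=k, replace=False)
    letters = list(sequence)
    for idx in chosen:
        i, j = pair_list[idx]
        a, b = CANONICAL_PAIRS[rng.integers(len(CANONICAL_PAIRS))]
        if rng.random() < 0.5:
            a, b = b, a
        letters[i], letters[j] = a, b
    return "".join(letters)


def mutate_base_pairs(
    s: StructureRecord, max_fraction: float = 0.10, rng_seed: int = 0
) -> StructureRecord:
    """Base-pair mutation augmentation on a structure record;
    deterministic given the seed."""
    rng = np.random.default_rng(rng_seed)
    seq = mutate_sequence_pairs(s.sequence, s.pairs, rng, max_fraction)
    return StructureRecord(RnaRecord(s.id, seq), s.pairs)
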