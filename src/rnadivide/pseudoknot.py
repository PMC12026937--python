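"""Pseudoknot detection, enumeration and removal.

A pseudoknot is formed by two nested groups of base pairs that cross:
every pair (i, j) of the first group and (k, l) of the second satisfies
i < k < j < l.  Removal follows the incremental-range (IR) criterion,
which prefers to keep the group spanning the longest sequence range,
i.e. long-range stems survive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .structure_io import PairSet

__all__ = [
    "HelixGroup",
    "Pseudoknot",
    "crossing_pairs",
    "crossing",
    "is_pk_free",
    "enumerate_pseudoknots",
    "remove_pseudoknots_ir",
]


def crossing(p: tuple, q: tuple) -> bool:
    """True iff the two pairs cross (i < k < j < l in either order)."""
    i, j = p
    k, l = q
    return (i < k < j < l) or (k < i < l < j)


def crossing_pairs(pairs) -> set[frozenset]:
    """All unordered crossing pair-of-pairs, by exhaustive check."""
    return {
        frozenset((p, q))
        for p, q in combinations(sorted(pairs), 2)
        if crossing(p, q)
    }


def is_pk_free(pairs) -> bool:
    """True iff no two pairs cross."""
    return not any(crossing(p, q) for p, q in combinations(sorted(pairs), 2))


@dataclass(frozen=True)
class HelixGroup:
    """Mutually nested base pairs acting as one duplex, sorted by
    increasing left index (hence decreasing right index)."""

    pairs: tuple

    def __post_init__(self):
        ps = tuple(sorted(self.pairs))
        for (i1, j1), (i2, j2) in zip(ps, ps[1:]):
            if not (i1 < i2 and j2 < j1):
                raise ValueError(f"pairs {ps} are not mutually nested")
        object.__setattr__(self, "pairs", ps)

    @property
    def min_left(self) -> int:
        return self.pairs[0][0]

    @property
    def range(self) -> int:
        """max j − min i over the group's pairs (its sequence span)."""
        return self.pairs[0][1] - self.pairs[0][0]


@dataclass(frozen=True)
class Pseudoknot:
    """Two crossing nested groups; first_group holds the smallest left
    index, so i < k < j < l reads left-to-right."""

    first_group: HelixGroup
    second_group: HelixGroup

    def __post_init__(self):
        for i, j in self.first_group.pairs:
            for k, l in self.second_group.pairs:
                if not i < k < j < l:
                    raise ValueError(
                        f"groups do not cross as a pseudoknot: "
                        f"({i},{j}) vs ({k},{l})"
                    )


def _nested_groups(pairs) -> list[HelixGroup]:
    """Partition crossing-involved pairs into maximal nested groups whose
    members share the same set of crossing partners.

    Pairs are processed by increasing left index; a pair joins an existing
    group when it nests strictly inside the group's innermost pair and
    crosses exactly the same opposing pairs.
    """
    pairs = sorted(pairs)
    cross_map = {p: set() for p in pairs}
    for p, q in combinations(pairs, 2):
        if crossing(p, q):
            cross_map[p].add(q)
            cross_map[q].add(p)
    involved = [p for p in pairs if cross_map[p]]
    groups: list[list[tuple]] = []
    keys: list[frozenset] = []
    for p in involved:
        key = frozenset(cross_map[p])
        placed = False
        for g, gkey in zip(groups, keys):
            inner = g[-1]
            if inner[0] < p[0] and p[1] < inner[1] and key == gkey:
                g.append(p)
                placed = True
                break
        if not placed:
            groups.append([p])
            keys.append(key)
    return [HelixGroup(tuple(g)) for g in groups]


def enumerate_pseudoknots(pairs) -> list[Pseudoknot]:
    """Enumerate pseudoknots as ordered pairs of crossing nested groups.

    One Pseudoknot is emitted per unordered pair of groups in which every
    cross-group combination satisfies i < k < j < l; the first group is
    the one containing the smallest left index.
    """
    groups = _nested_groups(pairs)
    out = []
    for a, b in combinations(groups, 2):
        first, second = (a, b) if a.min_left < b.min_left else (b, a)
        if all(
            i < k < j < l
            for i, j in first.pairs
            for k, l in second.pairs
        ):
            out.append(Pseudoknot(first, second))
    out.sort(key=lambda pk: (pk.first_group.pairs, pk.second_group.pairs))
    return out


def remove_pseudoknots_ir(pairs) -> PairSet:
    """Remove pseudoknots under the IR (incremental, range) criterion.

    While crossings remain, the conflicting helix group with the smallest
    range (max j − min i) is removed, so long-range stems are kept; ties
    remove the 3'-most group (larger left index).  The result is a
    crossing-free subset of the input.
    """
    work = set(pairs)
    while True:
        groups = _nested_groups(work)
        if not groups:
            return frozenset(work)
        victim = min(groups, key=lambda g: (g.range, -g.min_left))
        work.difference_update(victim.pairs)
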