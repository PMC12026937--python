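"""Synthetic RNA structures with known secondary structure.

The generator emulates the gross architecture of natural structured
RNAs: several top-level domains (stem-loops or small two-way multiloops)
separated by unpaired linkers, optionally wrapped by a long-range outer
stem pairing the 5' and 3' ends, and optionally carrying one H-type
pseudoknot (a helix crossing from a hairpin loop into a downstream
unpaired run).  Every pair is canonical (AU, GC or GU, random order);
unpaired letters are uniform.  Linkers and outer-stem spacers are at
least 4 nt so ideal cut labels always have room between stems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labelgen import CANONICAL_PAIRS
from .structure_io import RnaRecord, StructureRecord

__all__ = ["SynthConfig", "generate_structure", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    length_range: tuple = (200, 1200)
    n_domains_range: tuple = (2, 6)
    stem_length_range: tuple = (4, 12)
    loop_length_range: tuple = (3, 8)
    linker_length_range: tuple = (4, 12)
    tail_length_range: tuple = (0, 8)
    outer_spacer_range: tuple = (4, 8)
    pk_helix_length_range: tuple = (3, 6)
    p_outer_stem: float = 0.3
    p_pseudoknot: float = 0.3
    p_multiloop: float = 0.35

    def __post_init__(self):
        for p in (self.p_outer_stem, self.p_pseudoknot, self.p_multiloop):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for rng_ in (
            self.length_range,
            self.n_domains_range,
            self.stem_length_range,
            self.loop_length_range,
            self.linker_length_range,
            self.tail_length_range,
            self.outer_spacer_range,
            self.pk_helix_length_range,
        ):
            lo, hi = rng_
            if lo > hi or lo < 0:
                raise ValueError(f"infeasible range {rng_}")
        if self.linker_length_range[0] < 4:
            raise ValueError("linkers must be at least 4 nt")


def _draw(rng, r) -> int:
    return int(rng.integers(r[0], r[1] + 1))


def _stem_loop(rng, cfg: SynthConfig):
    """Returns (length, pairs, loop_runs) in local coordinates."""
    s = _draw(rng, cfg.stem_length_range)
    l = _draw(rng, cfg.loop_length_range)
    n = 2 * s + l
    pairs = {(t, n - 1 - t) for t in range(s)}
    return n, pairs, [(s, l)]


def _domain(rng, cfg: SynthConfig):
    """A stem-loop or a small two-way multiloop under an outer helix."""
    if rng.random() >= cfg.p_multiloop:
        return _stem_loop(rng, cfg)
    s = _draw(rng, cfg.stem_length_range)
    spacers = [int(rng.integers(2, 6)) for _ in range(3)]
    parts = []
    pairs = set()
    loop_runs = []
    off = s + spacers[0]
    for k in range(2):
        ln, sub_pairs, sub_loops = _stem_loop(rng, cfg)
        pairs |= {(i + off, j + off) for i, j in sub_pairs}
        loop_runs += [(a + off, b) for a, b in sub_loops]
        off += ln
        off += spacers[k + 1]
    n = off + s
    pairs |= {(t, n - 1 - t) for t in range(s)}
    return n, pairs, loop_runs


def generate_structure(
    cfg: SynthConfig, rng: np.random.Generator, uid: str = "synth"
) -> StructureRecord:
    """Draw one structure; deterministic given the generator state."""
    target = _draw(rng, cfg.length_range)
    k = _draw(rng, cfg.n_domains_range)
    domains = [_domain(rng, cfg) for _ in range(k)]
    linkers = [_draw(rng, cfg.linker_length_range) for _ in range(k - 1)]
    tails = [_draw(rng, cfg.tail_length_range) for _ in range(2)]
    outer = rng.random() < cfg.p_outer_stem
    outer_stem = _draw(rng, cfg.stem_length_range) if outer else 0
    spacers = (
        [_draw(rng, cfg.outer_spacer_range) for _ in range(2)] if outer else [0, 0]
    )

    def total() -> int:
        return (
            sum(d[0] for d in domains)
            + sum(linkers)
            + sum(tails)
            + 2 * outer_stem
            + sum(spacers)
        )

    while total() > cfg.length_range[1] and len(domains) > 1:
        domains.pop()
        if linkers:
            linkers.pop()

    # Pad unpaired runs (linkers, tails, spacers) up to the target length.
    slots = []
    slots += [("linker", i) for i in range(len(linkers))]
    slots += [("tail", 0), ("tail", 1)]
    if outer:
        slots += [("spacer", 0), ("spacer", 1)]
    deficit = max(target - total(), 0)
    if deficit and slots:
        extra = rng.multinomial(deficit, np.full(len(slots), 1.0 / len(slots)))
        for (kind, idx), e in zip(slots, extra):
            if kind == "linker":
                linkers[idx] += int(e)
            elif kind == "tail":
                tails[idx] += int(e)
            else:
                spacers[idx] += int(e)

    # Assemble: tail5 | [outer5 spacer5] | dom1 link1 dom2 ... | [spacer3 outer3] | tail3
    pairs = set()
    loop_runs = []  # (start, length) of hairpin loops, global coords
    unpaired_runs = []  # candidate downstream partners for a pseudoknot
    pos = tails[0]
    if outer:
        outer_start = pos
        pos += outer_stem + spacers[0]
    for di, (ln, dpairs, dloops) in enumerate(domains):
        pairs |= {(i + pos, j + pos) for i, j in dpairs}
        loop_runs += [(a + pos, b, di) for a, b in dloops]
        pos += ln
        if di < len(linkers):
            unpaired_runs.append((pos, linkers[di], di))
            pos += linkers[di]
    if outer:
        unpaired_runs.append((pos, spacers[1], len(domains) - 1))
        pos += spacers[1]
        n = pos + outer_stem + tails[1]
        pairs |= {
            (outer_start + t, pos + outer_stem - 1 - t) for t in range(outer_stem)
        }
        pos += outer_stem
    else:
        n = pos + tails[1]
    if tails[1] >= 4:
        unpaired_runs.append((pos, tails[1], len(domains) - 1))

    if rng.random() < cfg.p_pseudoknot:
        _insert_pseudoknot(rng, cfg, pairs, loop_runs, unpaired_runs)

    seq = _assign_sequence(rng, n, pairs)
    return StructureRecord(RnaRecord(uid, seq), frozenset(pairs))


def _insert_pseudoknot(rng, cfg, pairs, loop_runs, unpaired_runs):
    """Cross a hairpin loop with a downstream unpaired run (H-type)."""
    options = [
        (loop, run)
        for loop in loop_runs
        for run in unpaired_runs
        if run[2] >= loop[2] and run[0] > loop[0] + loop[1]
        and min(loop[1], run[1]) >= cfg.pk_helix_length_range[0]
    ]
    if not options:
        return
    loop, run = options[rng.integers(len(options))]
    t = min(
        _draw(rng, cfg.pk_helix_length_range), loop[1], run[1]
    )
    for a in range(t):
        i = loop[0] + a
        j = run[0] + (t - 1 - a)
        pairs.add((i, j))


def _assign_sequence(rng, n: int, pairs) -> str:
    letters = [
        "ACGU"[rng.integers(4)] for _ in range(n)
    ]
    for i, j in sorted(pairs):
        a, b = CANONICAL_PAIRS[rng.integers(len(CANONICAL_PAIRS))]
        if rng.random() < 0.5:
            a, b = b, a
        letters[i], letters[j] = a, b
    return "".join(letters)


def generate_dataset(
    cfg: SynthConfig, count: int, seed: int = 0
) -> list[StructureRecord]:
    """``count`` independent draws with unique ids, reproducible per seed."""
    children = np.random.SeedSequence(seed).spawn(count)
    return [
        generate_structure(
            cfg, np.random.default_rng(child), uid=f"synth_{k:05d}"
        )
        for k, child in enumerate(children)
    ]
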