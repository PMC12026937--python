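"""Per-nucleotide feature extraction.

A sequence is encoded as an n x (4 + m) matrix: one-hot channels for
A, C, G, U (an N yields an all-zero row) followed by one channel per
motif pattern.  A motif is a string of IUPAC nucleotide codes with '*'
wildcards, each '*' standing for one or more arbitrary nucleotides (gap
length capped for tractability).  The motif channel counts, for every
position, the number of match configurations in which that position is
covered by a literal (non-wildcard) motif character; counts are then
log1p-scaled so they stay bounded on long sequences.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MotifPattern",
    "one_hot",
    "motif_counts",
    "featurize",
    "feature_schema",
    "parse_motif_file",
    "load_default_motifs",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU",
    "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU",
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC + '*' wildcard pattern."""

    name: str
    pattern: str

    def __post_init__(self):
        p = self.pattern.upper().replace("T", "U")
        object.__setattr__(self, "pattern", p)
        if not p:
            raise ValueError("empty motif pattern")
        if p[0] == "*" or p[-1] == "*":
            raise ValueError(f"{self.name}: '*' may not start or end a pattern")
        if "**" in p:
            raise ValueError(f"{self.name}: adjacent '*' not allowed")
        bad = set(p) - set(IUPAC) - {"*"}
        if bad:
            raise ValueError(f"{self.name}: invalid pattern chars {sorted(bad)}")

    @property
    def segments(self) -> tuple[str, ...]:
        return tuple(self.pattern.split("*"))

    @property
    def n_literals(self) -> int:
        return len(self.pattern.replace("*", ""))


def _as_str(seq) -> str:
    return seq.sequence if hasattr(seq, "sequence") else seq


def one_hot(seq) -> np.ndarray:
    """n x 4 one-hot matrix over A, C, G, U; N rows are all zero."""
    seq = _as_str(seq)
    n = len(seq)
    out = np.zeros((n, 4), dtype=np.float64)
    for i, ch in enumerate(seq):
        k = _BASE_INDEX.get(ch)
        if k is not None:
            out[i, k] = 1.0
    return out


def _segment_occurrences(seq: str, segment: str) -> list[int]:
    """Start positions where the IUPAC segment matches (overlaps allowed)."""
    L = len(segment)
    classes = [IUPAC[c] for c in segment]
    return [
        s
        for s in range(len(seq) - L + 1)
        if all(seq[s + k] in classes[k] for k in range(L))
    ]


def _motif_column(seq: str, motif: MotifPattern, gap_cap: int) -> np.ndarray:
    """Per-position configuration counts for one motif.

    Configurations place the literal segments in order, separated by gaps
    of 1..gap_cap nucleotides per '*'.  The count at each position is the
    number of configurations covering it with a literal character,
    computed with a left/right placement-count dynamic program (equal to
    the naive enumeration, without materializing configurations).
    """
    n = len(seq)
    col = np.zeros(n, dtype=np.float64)
    segs = motif.segments
    occ = [_segment_occurrences(seq, s) for s in segs]
    if any(not o for o in occ):
        return col
    S = len(segs)
    # left[s][t] = number of ways to place segments 0..s with segment s
    # starting at occ[s][t]
    left = [np.ones(len(occ[0]))]
    for s in range(1, S):
        prev_end = np.array([o + len(segs[s - 1]) for o in occ[s - 1]])
        cur = np.zeros(len(occ[s]))
        for t, start in enumerate(occ[s]):
            gap = start - prev_end
            ok = (gap >= 1) & (gap <= gap_cap)
            cur[t] = left[s - 1][ok].sum()
        left.append(cur)
    right = [None] * S
    right[S - 1] = np.ones(len(occ[S - 1]))
    for s in range(S - 2, -1, -1):
        nxt_start = np.array(occ[s + 1])
        cur = np.zeros(len(occ[s]))
        seg_len = len(segs[s])
        for t, start in enumerate(occ[s]):
            gap = nxt_start - (start + seg_len)
            ok = (gap >= 1) & (gap <= gap_cap)
            cur[t] = right[s + 1][ok].sum()
        right[s] = cur
    for s in range(S):
        seg_len = len(segs[s])
        for t, start in enumerate(occ[s]):
            w = left[s][t] * right[s][t]
            if w:
                col[start : start + seg_len] += w
    return col


def motif_counts(seq, motifs, gap_cap: int = 30) -> np.ndarray:
    """n x m raw configuration-coverage counts, one column per motif."""
    seq = _as_str(seq)
    n = len(seq)
    out = np.zeros((n, len(motifs)), dtype=np.float64)
    for k, motif in enumerate(motifs):
        out[:, k] = _motif_column(seq, motif, gap_cap)
    return out


def featurize(seq, motifs=(), gap_cap: int = 30) -> np.ndarray:
    """Concatenate one-hot channels with log1p-scaled motif counts."""
    seq = _as_str(seq)
    oh = one_hot(seq)
    if not motifs:
        return oh
    return np.hstack([oh, np.log1p(motif_counts(seq, motifs, gap_cap))])


def feature_schema(motifs=()) -> list[str]:
    """Column names; stored with model weights to refuse mismatched input."""
    return ["onehot:A", "onehot:C", "onehot:G", "onehot:U"] + [
        f"motif:{m.name}:{m.pattern}" for m in motifs
    ]


def motifs_from_schema(schema) -> list[MotifPattern]:
    out = []
    for col in schema:
        if col.startswith("motif:"):
            _, name, pattern = col.split(":", 2)
            out.append(MotifPattern(name, pattern))
    return out


def parse_motif_file(text: str) -> list[MotifPattern]:
    """One 'name<TAB>pattern' per line; '#' starts a comment."""
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        ln = raw.split("#", 1)[0].strip()
        if not ln:
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise ValueError(f"motif file line {lineno}: expected name<TAB>pattern")
        out.append(MotifPattern(parts[0], parts[1]))
    return out


def load_default_motifs() -> list[MotifPattern]:
    """The small default motif set shipped with the package."""
    text = (
        importlib.resources.files("rnadivide")
        .joinpath("data/default_motifs.tsv")
        .read_text()
    )
    return parse_motif_file(text)
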