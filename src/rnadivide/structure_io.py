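"""Reading and writing RNA sequences and secondary structures.

The canonical in-memory representation of a secondary structure is a
*pair set*: a ``frozenset`` of 0-based ``(i, j)`` index tuples with
``i < j``, each position belonging to at most one pair.  Supported text
formats are FASTA, bpRNA-dialect dot-bracket (three lines per record,
multi-level brackets for pseudoknots), bpseq and CT.
"""

from __future__ import annotations

import io
import string
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "RnaRecord",
    "StructureRecord",
    "PairSet",
    "ParseError",
    "as_pairset",
    "clean_sequence",
    "read_fasta",
    "write_fasta",
    "read_dotbracket",
    "write_dotbracket",
    "read_bpseq",
    "write_bpseq",
    "read_ct",
    "write_ct",
]

PairSet = frozenset  # of (i, j) tuples, 0-based, i < j

ALPHABET = frozenset("ACGUN")

# Bracket pages, in greedy-assignment order.  Level 0 is round brackets;
# pseudoknotted helices overflow onto later pages.
_PAGES = ["()", "[]", "{}", "<>"] + [
    o + c for o, c in zip(string.ascii_uppercase, string.ascii_lowercase)
]
_OPEN_TO_LEVEL = {p[0]: lvl for lvl, p in enumerate(_PAGES)}
_CLOSE_TO_LEVEL = {p[1]: lvl for lvl, p in enumerate(_PAGES)}


class ParseError(ValueError):
    """Raised when a structure or sequence file cannot be parsed."""


def clean_sequence(seq: str) -> str:
    """Uppercase, normalize T to U, and validate the alphabet."""
    out = seq.upper().replace("T", "U")
    bad = set(out) - ALPHABET
    if bad:
        raise ParseError(f"invalid sequence characters: {sorted(bad)}")
    if not out:
        raise ParseError("empty sequence")
    return out


def as_pairset(pairs, n: int | None = None) -> PairSet:
    """Validate and freeze an iterable of (i, j) pairs.

    Each index may participate in at most one pair; ``i < j`` is enforced
    and, when ``n`` is given, all indices must be below ``n``.
    """
    seen: dict[int, tuple] = {}
    out = set()
    for p in pairs:
        i, j = int(p[0]), int(p[1])
        if i >= j:
            raise ValueError(f"pair ({i}, {j}) must satisfy i < j")
        if i < 0 or (n is not None and j >= n):
            raise ValueError(f"pair ({i}, {j}) out of range for n={n}")
        for k in (i, j):
            if k in seen and seen[k] != (i, j):
                raise ValueError(
                    f"position {k} paired twice: {seen[k]} and ({i}, {j})"
                )
            seen[k] = (i, j)
        out.add((i, j))
    return frozenset(out)


@dataclass(frozen=True)
class RnaRecord:
    """An RNA sequence over {A, C, G, U, N} with an identifier."""

    id: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(self, "sequence", clean_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class StructureRecord:
    """A sequence together with its set of base pairs."""

    record: RnaRecord
    pairs: PairSet = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(
            self, "pairs", as_pairset(self.pairs, len(self.record))
        )

    @property
    def id(self) -> str:
        return self.record.id

    @property
    def sequence(self) -> str:
        return self.record.sequence

    def __len__(self) -> int:
        return len(self.record)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(text: str) -> list[RnaRecord]:
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise ParseError("no FASTA records found")
    return [RnaRecord(r.id, str(r.seq)) for r in records]


def write_fasta(records) -> str:
    lines = []
    for r in records:
        lines.append(f">{r.id}")
        lines.append(r.sequence)
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Dot-bracket (.dbn)

def _parse_structure_line(struct: str, lineno: int) -> PairSet:
    stacks: dict[int, list[int]] = {}
    pairs = set()
    for pos, ch in enumerate(struct):
        if ch == ".":
            continue
        if ch in _OPEN_TO_LEVEL:
            stacks.setdefault(_OPEN_TO_LEVEL[ch], []).append(pos)
        elif ch in _CLOSE_TO_LEVEL:
            lvl = _CLOSE_TO_LEVEL[ch]
            stack = stacks.get(lvl)
            if not stack:
                raise ParseError(
                    f"line {lineno}: unbalanced closing bracket "
                    f"{ch!r} (level {lvl}) at position {pos}"
                )
            pairs.add((stack.pop(), pos))
        else:
            raise ParseError(
                f"line {lineno}: unknown structure character {ch!r}"
            )
    for lvl, stack in stacks.items():
        if stack:
            raise ParseError(
                f"line {lineno}: {len(stack)} unclosed bracket(s) at "
                f"level {lvl} (positions {stack})"
            )
    return frozenset(pairs)


def read_dotbracket(text: str) -> list[StructureRecord]:
    """Parse dbn text: one header line, a sequence line and a structure
    line per record.  Headers start with '>' or '#'."""
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(text.splitlines())]
    lines = [(no, ln) for no, ln in lines if ln]
    out = []
    k = 0
    idx = 0
    while k < len(lines):
        no, header = lines[k]
        if header[0] in ">#":
            name = header.lstrip(">#").strip().split()[0] if header.lstrip(">#").strip() else f"record_{idx}"
            k += 1
        else:
            name = f"record_{idx}"
        if k + 1 >= len(lines):
            raise ParseError(f"line {no}: truncated dbn record {name!r}")
        seq_no, seq = lines[k]
        struct_no, struct = lines[k + 1]
        k += 2
        if len(seq) != len(struct):
            raise ParseError(
                f"line {struct_no}: structure length {len(struct)} does not "
                f"match sequence length {len(seq)} in record {name!r}"
            )
        pairs = _parse_structure_line(struct, struct_no)
        out.append(StructureRecord(RnaRecord(name, seq), pairs))
        idx += 1
    if not out:
        raise ParseError("no dbn records found")
    return out


def _crosses(p: tuple, q: tuple) -> bool:
    i, j = p
    k, l = q
    return (i < k < j < l) or (k < i < l < j)


def pairs_to_dotbracket(pairs, n: int) -> str:
    """Render a pair set as a dot-bracket string, assigning crossing pairs
    to distinct bracket levels by greedy page assignment (pairs processed
    by increasing left index)."""
    chars = ["."] * n
    pages: list[list[tuple]] = []
    for pair in sorted(pairs):
        for lvl, page in enumerate(pages):
            if not any(_crosses(pair, q) for q in page):
                break
        else:
            lvl = len(pages)
            if lvl >= len(_PAGES):
                raise ValueError(
                    f"structure needs more than {len(_PAGES)} bracket levels"
                )
            pages.append([])
        pages[lvl].append(pair)
        chars[pair[0]] = _PAGES[lvl][0]
        chars[pair[1]] = _PAGES[lvl][1]
    return "".join(chars)


def write_dotbracket(structures) -> str:
    """Write one or several StructureRecords as dbn text."""
    if isinstance(structures, StructureRecord):
        structures = [structures]
    lines = []
    for s in structures:
        lines.append(f">{s.id}")
        lines.append(s.sequence)
        lines.append(pairs_to_dotbracket(s.pairs, len(s)))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# bpseq / CT

def _reconcile_partners(partner: dict[int, int], n: int) -> PairSet:
    bad = sorted(
        i for i, p in partner.items() if p and partner.get(p, 0) != i
    )
    if bad:
        raise ParseError(
            f"inconsistent reciprocal partners at 1-based positions {bad}"
        )
    return as_pairset(
        ((i - 1, p - 1) for i, p in partner.items() if p and i < p), n
    )


def read_bpseq(text: str, name: str = "bpseq") -> StructureRecord:
    """Parse bpseq: one '<index> <base> <partner>' line per position,
    1-based indices, partner 0 meaning unpaired."""
    bases: dict[int, str] = {}
    partner: dict[int, int] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        ln = raw.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        if len(parts) != 3:
            raise ParseError(f"line {lineno}: expected 3 bpseq columns")
        i, base, p = int(parts[0]), parts[1], int(parts[2])
        if i in bases:
            raise ParseError(f"line {lineno}: duplicate index {i}")
        bases[i] = base
        partner[i] = p
    if not bases:
        raise ParseError("no bpseq rows found")
    n = max(bases)
    if sorted(bases) != list(range(1, n + 1)):
        raise ParseError("bpseq indices are not contiguous from 1")
    seq = "".join(bases[i] for i in range(1, n + 1))
    return StructureRecord(
        RnaRecord(name, seq), _reconcile_partners(partner, n)
    )


def write_bpseq(s: StructureRecord) -> str:
    partner = [0] * len(s)
    for i, j in s.pairs:
        partner[i] = j + 1
        partner[j] = i + 1
    return "\n".join(
        f"{k + 1} {s.sequence[k]} {partner[k]}" for k in range(len(s))
    ) + "\n"


def read_ct(text: str) -> StructureRecord:
    """Parse a 6-column CT file (index, base, prev, next, partner, index)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (ValueError, IndexError):
        raise ParseError("CT header must start with the sequence length")
    name = head[1] if len(head) > 1 else "ct"
    if len(lines) - 1 != n:
        raise ParseError(
            f"CT header declares {n} rows but {len(lines) - 1} found"
        )
    bases = []
    partner: dict[int, int] = {}
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split()
        if len(parts) < 6:
            raise ParseError(f"line {lineno}: expected 6 CT columns")
        i = int(parts[0])
        bases.append(parts[1])
        partner[i] = int(parts[4])
    seq = "".join(bases)
    return StructureRecord(
        RnaRecord(name, seq), _reconcile_partners(partner, n)
    )


def write_ct(s: StructureRecord) -> str:
    n = len(s)
    partner = [0] * n
    for i, j in s.pairs:
        partner[i] = j + 1
        partner[j] = i + 1
    lines = [f"{n} {s.id}"]
    for k in range(n):
        lines.append(
            f"{k + 1} {s.sequence[k]} {k} {k + 2 if k + 1 < n else 0} "
            f"{partner[k]} {k + 1}"
        )
    return "\n".join(lines) + "\n"
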