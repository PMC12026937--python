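"""Evaluation metrics: base-pair and pseudoknot precision/recall/F-score,
compression rate and break rate.

Pseudoknot matching follows the shared-pair rule: a predicted pseudoknot
is a true positive when some reference pseudoknot shares at least one
base pair with its first group and at least one with its second group
(first group = the one with the smaller minimum left index).  Matching
is many-to-many; no assignment problem is solved.

The break rate excludes pseudoknots: its denominator is the structure
after IR pseudoknot removal, its numerator those pairs whose endpoints
land in different fragments.  The compression rate 1 - sum((n_i/n)^2)
is 0 for a single fragment and grows toward 1 with many equal fragments.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pseudoknot import enumerate_pseudoknots, remove_pseudoknots_ir
from .structure_io import StructureRecord

__all__ = [
    "PRF",
    "bp_scores",
    "pk_scores",
    "compression_rate",
    "break_rate",
    "evaluate_pair",
]


@dataclass(frozen=True)
class PRF:
    precision: float
    recall: float
    fscore: float
    tp: int
    fp: int
    fn: int
    degenerate: bool = False  # a denominator was empty; metric reported as 0


def _prf(tp: int, fp: int, fn: int) -> PRF:
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return PRF(p, r, f, tp, fp, fn, degenerate)


def bp_scores(pred, truth) -> PRF:
    """Base-pair precision/recall/F over exact (i, j) matches."""
    pred, truth = set(pred), set(truth)
    tp = len(pred & truth)
    return _prf(tp, len(pred - truth), len(truth - pred))


def _similar(pk_a, pk_b) -> bool:
    return bool(
        set(pk_a.first_group.pairs) & set(pk_b.first_group.pairs)
    ) and bool(
        set(pk_a.second_group.pairs) & set(pk_b.second_group.pairs)
    )


def pk_scores(pred, truth) -> PRF:
    """Pseudoknot-level precision/recall/F under the shared-pair rule."""
    pred_pks = enumerate_pseudoknots(pred)
    truth_pks = enumerate_pseudoknots(truth)
    tp = sum(
        1 for p in pred_pks if any(_similar(p, t) for t in truth_pks)
    )
    fp = len(pred_pks) - tp
    fn = sum(
        1 for t in truth_pks if not any(_similar(p, t) for p in pred_pks)
    )
    return _prf(tp, fp, fn)


def _check_cover(fragments, n: int):
    covered = sorted(iv for f in fragments for iv in f.intervals)
    pos = 0
    for a, b in covered:
        if a != pos:
            raise ValueError(f"fragments do not cover [0, {n}) exactly")
        pos = b
    if pos != n:
        raise ValueError(f"fragments cover [0, {pos}) instead of [0, {n})")


def compression_rate(fragments, n: int) -> float:
    """1 - sum((n_i / n)^2) over fragment total lengths."""
    _check_cover(fragments, n)
    return 1.0 - sum((f.total_length / n) ** 2 for f in fragments)


def break_rate(truth: StructureRecord, fragments) -> float:
    """Fraction of non-pseudoknot pairs broken by the partition (both
    endpoints in different fragments); 0 when the depseudoknotted
    structure has no pairs."""
    _check_cover(fragments, len(truth))
    pairs = remove_pseudoknots_ir(truth.pairs)
    if not pairs:
        return 0.0
    frag_of = {}
    for k, f in enumerate(fragments):
        for a, b in f.intervals:
            for pos in range(a, b):
                frag_of[pos] = k
    broken = sum(1 for i, j in pairs if frag_of[i] != frag_of[j])
    return broken / len(pairs)


def evaluate_pair(pred: StructureRecord, truth: StructureRecord) -> dict:
    """Per-record report: base-pair and pseudoknot P/R/F."""
    if len(pred) != len(truth):
        raise ValueError("prediction and reference lengths differ")
    bp = bp_scores(pred.pairs, truth.pairs)
    pk = pk_scores(pred.pairs, truth.pairs)
    return {
        "id": truth.id,
        "n": len(truth),
        "bp": {"precision": bp.precision, "recall": bp.recall, "fscore": bp.fscore},
        "pk": {
            "precision": pk.precision,
            "recall": pk.recall,
            "fscore": pk.fscore,
            "no_pseudoknots": pk.degenerate,
        },
    }
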