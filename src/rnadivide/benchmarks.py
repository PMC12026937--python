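"""Reproducible benchmark experiments on synthetic structures.

These routines tie the other modules into the experiments the package
is validated with: zero-breakage of ideal labels, oracle end-to-end
recall, and the trained-model vs uniform-random-cuts break-rate
comparison.  Everything is generated programmatically and seeded, so
the same call reproduces the same numbers.
"""

from __future__ import annotations

import numpy as np

from .divide_model import DivideModel, ModelConfig, TrainConfig, train
from .features import load_default_motifs
from .labelgen import ideal_cut_points, recursive_training_examples
from .metrics import break_rate, compression_rate
from .partition import (
    NotDivisibleError,
    PeakParams,
    make_fragments,
    recursive_partition,
    uniform_random_cuts,
)
from .predict_recombine import (
    OraclePredictor,
    dividefold_predict,
    ideal_cutter,
    model_cutter,
)
from .pseudoknot import crossing
from .synthetic import SynthConfig, generate_dataset

__all__ = [
    "label_break_rates",
    "oracle_recall",
    "make_labeled_examples",
    "train_break_rate_experiment",
]


def label_break_rates(structures) -> list[float]:
    """Break rate of the ideal-label partition of each structure (one
    iteration of make_fragments on ideal_cut_points); structures with no
    safe cuts stay whole and score 0 by definition."""
    rates = []
    for s in structures:
        cuts = ideal_cut_points(s)
        if cuts:
            rates.append(break_rate(s, make_fragments(len(s), cuts)))
        else:
            rates.append(0.0)
    return rates


def oracle_recall(structures, max_len: int = 500) -> dict:
    """End-to-end check with ideal cuts and the oracle predictor.

    Returns per-structure recall on non-pseudoknot pairs and verifies
    every missing pair crosses another pair (i.e. is a pseudoknot pair
    split across fragments).
    """
    recalls = []
    non_pk_misses = 0
    for s in structures:
        pred, _ = dividefold_predict(
            s, ideal_cutter(s), OraclePredictor(s), max_len=max_len
        )
        non_pk = {
            p for p in s.pairs
            if not any(crossing(p, q) for q in s.pairs if q != p)
        }
        recalls.append(
            len(non_pk & pred.pairs) / len(non_pk) if non_pk else 1.0
        )
        for p in s.pairs - pred.pairs:
            if p in non_pk:
                non_pk_misses += 1
    return {"recalls": recalls, "non_pseudoknot_misses": non_pk_misses}


def make_labeled_examples(
    n_examples: int, seed: int, max_len: int = 500,
    cfg: SynthConfig | None = None,
):
    """Labeled training examples expanded recursively from synthetic
    structures; structures are drawn until ``n_examples`` are collected."""
    cfg = cfg or SynthConfig()
    examples = []
    chunk, offset = 100, 0
    while len(examples) < n_examples:
        for s in generate_dataset(cfg, chunk, seed=seed + offset):
            examples.extend(recursive_training_examples(s, max_len=max_len))
            if len(examples) >= n_examples:
                break
        offset += 1
    return examples[:n_examples]


def train_break_rate_experiment(
    seed: int = 7,
    n_examples: int = 300,
    epochs: int = 20,
    n_test: int = 100,
    max_len: int = 500,
    cfg: SynthConfig | None = None,
) -> dict:
    """Train the divide model and compare its partitions against a
    uniform-random-cuts baseline matched for cut count.

    The baseline asks the trained cutter how many cuts it would place on
    each recursion node's sequence and places that many uniform-random
    admissible cuts under the same margin/separation constraints.  Test
    structures are held out (disjoint seed stream).
    """
    cfg = cfg or SynthConfig()
    examples = make_labeled_examples(n_examples, seed, max_len=max_len, cfg=cfg)
    motifs = tuple(load_default_motifs())
    model, log = train(
        examples, ModelConfig(), TrainConfig(epochs=epochs, seed=seed),
        motifs=motifs,
    )
    test = generate_dataset(cfg, n_test, seed=seed + 1000)
    params = PeakParams()
    cutter = model_cutter(model, params)
    rng = np.random.default_rng(seed)

    def random_matched(sub_seq, frag=None):
        try:
            k = len(cutter(sub_seq, frag))
        except NotDivisibleError:
            k = 2
        return uniform_random_cuts(len(sub_seq), k, rng, params)

    model_rates, random_rates, compressions = [], [], []
    for s in test:
        rm = recursive_partition(s.sequence, cutter, max_len=max_len)
        rr = recursive_partition(s.sequence, random_matched, max_len=max_len)
        model_rates.append(break_rate(s, rm.fragments))
        random_rates.append(break_rate(s, rr.fragments))
        compressions.append(compression_rate(rm.fragments, len(s)))
    return {
        "model": model,
        "log": log,
        "model_break_rate": float(np.mean(model_rates)),
        "random_break_rate": float(np.mean(random_rates)),
        "model_compression": float(np.mean(compressions)),
        "n_examples": len(examples),
        "n_test": n_test,
    }
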