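"""Apply a short-RNA structure predictor per fragment and recombine.

A predictor is a callable ``(fragment_sequence, fragment) -> PairSet``
returning fragment-local 0-based pairs; sequence-only predictors may
ignore the fragment argument.  Merged discontinuous fragments are
presented as plain concatenations (no separator symbol), so a predictor
may pair across the junction — such pairs are kept and mapped back.
"""

from __future__ import annotations

import logging
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

from .partition import Fragment, PeakParams, recursive_partition, select_cut_points
from .structure_io import (
    RnaRecord,
    StructureRecord,
    as_pairset,
    read_ct,
    read_dotbracket,
    _parse_structure_line,
)

__all__ = [
    "OraclePredictor",
    "null_predictor",
    "ExternalCommandPredictor",
    "predict_fragments",
    "recombine",
    "dividefold_predict",
    "model_cutter",
    "ideal_cutter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OraclePredictor:
    """Test oracle standing in for a real short-RNA predictor: returns
    exactly the reference pairs whose both endpoints lie inside the
    fragment, reindexed to fragment-local coordinates."""

    reference: StructureRecord

    def __call__(self, fragment_seq: str, fragment: Fragment) -> frozenset:
        return fragment.induced_pairs(self.reference.pairs)


def null_predictor(fragment_seq: str, fragment: Fragment) -> frozenset:
    """Predicts no structure at all."""
    return frozenset()


_DBN_CHARS = set(".()[]{}<>") | set(
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
)


@dataclass(frozen=True)
class ExternalCommandPredictor:
    """Shell-out adapter for external predictors (e.g. KnotFold, IPknot).

    ``command`` is a shell template; ``{fasta}`` is replaced by the path
    of a single-record FASTA holding the fragment sequence.  The
    structure is read from stdout: the first line made of dot-bracket
    characters of the right length (trailing energies are stripped), or a
    whole CT table when ``output_format='ct'``.
    """

    command: str
    timeout: float = 300.0
    output_format: str = "dbn"

    def __call__(self, fragment_seq: str, fragment: Fragment) -> frozenset:
        with tempfile.TemporaryDirectory() as tmp:
            fasta = Path(tmp) / "fragment.fa"
            fasta.write_text(f">fragment\n{fragment_seq}\n")
            cmd = self.command.replace("{fasta}", shlex.quote(str(fasta)))
            proc = subprocess.run(
                cmd, shell=True, capture_output=True, text=True,
                timeout=self.timeout,
            )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external predictor failed ({proc.returncode}): "
                f"{proc.stderr.strip()[:500]}"
            )
        if self.output_format == "ct":
            return read_ct(proc.stdout).pairs
        n = len(fragment_seq)
        for raw in proc.stdout.splitlines():
            token = raw.strip().split()[0] if raw.strip() else ""
            if len(token) == n and set(token) <= _DBN_CHARS and (
                "." in token or "(" in token
            ):
                return _parse_structure_line(token, 0)
        raise RuntimeError("no dot-bracket line of matching length in output")


def predict_fragments(fragments, sequence: str, predictor) -> list[frozenset]:
    """One fragment-local PairSet per fragment; a predictor failure on a
    fragment yields an empty set with a logged warning."""
    out = []
    for frag in fragments:
        sub = frag.extract(sequence)
        try:
            pairs = as_pairset(predictor(sub, frag), len(sub))
        except Exception as exc:  # noqa: BLE001 - predictor is third-party
            logger.warning(
                "predictor failed on fragment %s: %s", frag.intervals, exc
            )
            pairs = frozenset()
        out.append(pairs)
    return out


def recombine(fragment_pairsets, fragments) -> frozenset:
    """Map fragment-local pairs back to original coordinates and union.

    Fragments are disjoint, so no position can be paired by two
    fragments; the merged result is validated as a proper pair set.
    """
    if len(fragment_pairsets) != len(fragments):
        raise ValueError("one PairSet per fragment required")
    merged = set()
    for pairs, frag in zip(fragment_pairsets, fragments):
        for i, j in pairs:
            try:
                gi, gj = frag.local_to_global(i), frag.local_to_global(j)
            except IndexError as exc:
                raise IndexError(
                    f"pair ({i}, {j}) out of range in fragment "
                    f"{frag.intervals}"
                ) from exc
            merged.add((min(gi, gj), max(gi, gj)))
    return as_pairset(merged)


def model_cutter(model, peak_params: PeakParams | None = None):
    """Wrap a divide model into the cutter contract used by
    recursive_partition: sequence -> cut points."""
    params = peak_params or PeakParams()

    def cutter(sub_seq: str, fragment=None):
        return select_cut_points(model.predict_sequence(sub_seq), params)

    return cutter


def ideal_cutter(reference: StructureRecord):
    """A structure-aware cutter that places the ideal (label) cut points
    for any fragment of the reference structure; raises NotDivisibleError
    when a fragment has no safe cuts."""
    from .labelgen import ideal_cut_points_from_pairs
    from .partition import NotDivisibleError

    def cutter(sub_seq: str, fragment: Fragment):
        cuts = ideal_cut_points_from_pairs(
            len(sub_seq), fragment.induced_pairs(reference.pairs)
        )
        if not cuts:
            raise NotDivisibleError("no safe ideal cut points")
        return cuts

    return cutter


def dividefold_predict(
    record,
    model,
    predictor,
    max_len: int = 1000,
    peak_params: PeakParams | None = None,
):
    """Full workflow: partition recursively with the divide model, predict
    each fragment with the supplied structure predictor, recombine into a
    global structure.  Sequences no longer than ``max_len`` go to the
    predictor whole.

    ``model`` may be a DivideModel or any ``sequence -> cut points``
    callable.  Returns (StructureRecord, PartitionResult).
    """
    if isinstance(record, str):
        record = RnaRecord("query", record)
    cutter = model if callable(model) else model_cutter(model, peak_params)
    result = recursive_partition(record.sequence, cutter, max_len=max_len)
    pairsets = predict_fragments(result.fragments, record.sequence, predictor)
    pairs = recombine(pairsets, result.fragments)
    return StructureRecord(record, pairs), result
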