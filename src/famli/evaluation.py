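"""Benchmarking harness: TP/FP/DUP classification of detected CDS.

Detected and truly-present peptide sets are each clustered at 90% amino acid
identity (so a family of near-identical homologs counts once), then compared
all-vs-all by local alignment.  A detected CDS is a true positive when it and
a truth are each other's best hits (mutual best hit), a duplicate when it
aligns to a truth without being that truth's best detected hit, and a false
positive when it aligns to no truth at all.  Truths with no true-positive
partner are false negatives.  From the counts:

    sensitivity = TP / (TP + FN)
    PPV         = TP / (TP + FP)
    uniqueness  = TP / (TP + DUP)

optionally stratified by the true CDS's sequencing depth (e.g. the 0-5x bin,
where mapping- and assembly-based approaches differ most).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import edlib

from ._align import SeedIndex, align_local, make_protein_aligner

DEFAULT_DEPTH_BINS: tuple[tuple[float, float], ...] = ((0.0, 5.0), (5.0, math.inf))


def global_identity(a: str, b: str) -> float:
    """Global (end-to-end) identity of two sequences, computed from the
    Levenshtein distance as 1 - d / max(len); 0 for an empty pair."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - d / max(len(a), len(b)))


def cluster_90(
    peptides: Mapping[str, str],
    identity: float = 0.9,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy longest-first clustering (CD-HIT style).

    Sequences are visited longest first (ties by id); each joins the first
    existing representative it matches at >= ``identity`` global identity,
    otherwise it founds a new cluster.  Returns (representatives, membership)
    where ``representatives`` maps representative id -> sequence and
    ``membership`` maps every input id -> its representative id.
    Deterministic for a given input set.
    """
    if not peptides:
        raise ValueError("empty peptide set")
    order = sorted(peptides, key=lambda sid: (-len(peptides[sid]), sid))
    reps: dict[str, str] = {}
    membership: dict[str, str] = {}
    for sid in order:
        seq = peptides[sid]
        for rep_id, rep_seq in reps.items():
            if global_identity(seq, rep_seq) >= identity:
                membership[sid] = rep_id
                break
        else:
            reps[sid] = seq
            membership[sid] = sid
    return reps, membership


@dataclass
class EvaluationLabels:
    """Per-detection classification plus per-truth detection status."""

    labels: dict[str, str] = field(default_factory=dict)  # det id -> TP/FP/DUP
    matched_truth: dict[str, str] = field(default_factory=dict)  # det -> top truth
    truth_detected: dict[str, bool] = field(default_factory=dict)

    @property
    def tp(self) -> int:
        return sum(1 for v in self.labels.values() if v == "TP")

    @property
    def fp(self) -> int:
        return sum(1 for v in self.labels.values() if v == "FP")

    @property
    def dup(self) -> int:
        return sum(1 for v in self.labels.values() if v == "DUP")

    @property
    def fn(self) -> int:
        return sum(1 for v in self.truth_detected.values() if not v)


def classify_detections(
    detected: Mapping[str, str],
    truth: Mapping[str, str],
    *,
    min_identity: float = 0.5,
    min_coverage: float = 0.5,
    seed_k: int = 5,
) -> EvaluationLabels:
    """Label every detected CDS as TP, FP or DUP against the truth set.

    Both sets are expected to be pre-clustered representatives.  "Aligns
    against" means a local alignment with >= ``min_identity`` identity
    covering >= ``min_coverage`` of the shorter sequence; below that floor a
    detected CDS counts as aligning to nothing.  Best hits are ordered by raw
    alignment score, then identity, then id (for determinism); a detection is
    TP only if it is also the best-scoring detected hit of its top truth.
    """
    labels = EvaluationLabels(
        truth_detected={tid: False for tid in truth}
    )
    if not detected:
        return labels
    if not truth:
        labels.labels = {did: "FP" for did in detected}
        return labels

    index = SeedIndex(truth, k=seed_k)
    aligner = make_protein_aligner()

    # det -> best truth, and per-truth best detected, over all qualifying hits
    det_best: dict[str, tuple[float, float, str]] = {}
    truth_best: dict[str, tuple[float, float, str]] = {}
    for did in sorted(detected):
        dseq = detected[did]
        for tid in index.candidates(dseq):
            hit = align_local(aligner, dseq, tid, truth[tid])
            if hit is None or hit.identity < min_identity:
                continue
            shorter = min(len(dseq), len(truth[tid]))
            span = min(
                hit.query_end - hit.query_start + 1,
                hit.subject_end - hit.subject_start + 1,
            )
            if span < min_coverage * shorter:
                continue
            key = (hit.raw_score, hit.identity)
            prev = det_best.get(did)
            if prev is None or key > prev[:2] or (key == prev[:2] and tid < prev[2]):
                det_best[did] = (*key, tid)
            prev_t = truth_best.get(tid)
            if prev_t is None or key > prev_t[:2] or (key == prev_t[:2] and did < prev_t[2]):
                truth_best[tid] = (*key, did)

    for did in detected:
        if did not in det_best:
            labels.labels[did] = "FP"
            continue
        top_truth = det_best[did][2]
        labels.matched_truth[did] = top_truth
        if truth_best[top_truth][2] == did:
            labels.labels[did] = "TP"
            labels.truth_detected[top_truth] = True
        else:
            labels.labels[did] = "DUP"
    return labels


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


@dataclass
class MetricReport:
    """Overall and depth-stratified detection metrics.

    ``None`` marks an undefined metric (empty denominator), never 0.
    """

    tp: int
    fp: int
    dup: int
    fn: int
    sensitivity: float | None
    ppv: float | None
    uniqueness: float | None
    stratified: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "dup": self.dup, "fn": self.fn,
            "sensitivity": self.sensitivity, "ppv": self.ppv,
            "uniqueness": self.uniqueness, "stratified": self.stratified,
        }


def _bin_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}x" if math.isfinite(hi) else f">{lo:g}x"


def compute_metrics(
    labels: EvaluationLabels,
    truth_depths: Mapping[str, float] | None = None,
    depth_bins: Sequence[tuple[float, float]] = DEFAULT_DEPTH_BINS,
) -> MetricReport:
    """Sensitivity, PPV and uniqueness from TP/FP/DUP/FN counts.

    When per-truth depths are supplied, each (lo, hi] bin restricts TP and FN
    to truths whose depth falls in the bin (and DUP to duplicates of such
    truths); FP carries no true depth and enters every bin's PPV unchanged.
    """
    tp, fp, dup, fn = labels.tp, labels.fp, labels.dup, labels.fn
    report = MetricReport(
        tp=tp, fp=fp, dup=dup, fn=fn,
        sensitivity=_ratio(tp, tp + fn),
        ppv=_ratio(tp, tp + fp),
        uniqueness=_ratio(tp, tp + dup),
    )
    if truth_depths is None:
        return report

    for lo, hi in depth_bins:
        in_bin = {
            tid for tid in labels.truth_detected
            if tid in truth_depths and lo < truth_depths[tid] <= hi
        }
        tp_bin = sum(1 for tid in in_bin if labels.truth_detected[tid])
        fn_bin = len(in_bin) - tp_bin
        dup_bin = sum(
            1
            for did, lab in labels.labels.items()
            if lab == "DUP" and labels.matched_truth.get(did) in in_bin
        )
        report.stratified[_bin_label(lo, hi)] = {
            "tp": tp_bin, "fn": fn_bin, "dup": dup_bin,
            "sensitivity": _ratio(tp_bin, tp_bin + fn_bin),
            "ppv": _ratio(tp_bin, tp_bin + fp),
            "uniqueness": _ratio(tp_bin, tp_bin + dup_bin),
        }
    return report
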