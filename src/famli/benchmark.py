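"""End-to-end benchmark scenarios built from the synthetic generators.

Two scenarios are provided:

* :func:`multimapping_experiment` -- the controlled design for studying
  multi-mapped read resolution: a handful of true CDS, each surrounded by a
  family of decoy homologs sharing a conserved domain, with a fixed number of
  read pairs per CDS.  Ground truth makes per-read correctness directly
  checkable.

* :func:`community_benchmark` -- a full simulated community run through
  the filter and through two mapping baselines (all-hits, unique-hits), each
  evaluated with the TP/FP/DUP harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .alignment_io import AlignmentSet, accept_best
from .core import FamliParams, FamliResult, run_famli
from .evaluation import MetricReport, classify_detections, cluster_90, compute_metrics
from .simulate import (
    CommunityTruth,
    SimParams,
    make_homolog_family,
    make_community,
    emulate_translated_alignment,
    simulate_reads,
)


def alignment_table_to_set(table: pd.DataFrame) -> AlignmentSet:
    """Convert the emulated aligner's DataFrame into a validated
    :class:`AlignmentSet` (mate suffixes stripped, pairs deduplicated)."""
    from .alignment_io import AlignmentRecord

    records = [
        AlignmentRecord(
            query_id=row.qseqid,
            subject_id=row.sseqid,
            percent_identity=row.pident,
            align_length=int(row.length),
            mismatches=int(row.mismatch),
            gap_opens=int(row.gapopen),
            query_start=int(row.qstart),
            query_end=int(row.qend),
            subject_start=int(row.sstart),
            subject_end=int(row.send),
            evalue=row.evalue,
            bitscore=row.bitscore,
        )
        for row in table.itertuples()
    ]
    lengths = dict(zip(table["sseqid"], table["slen"].astype(int)))
    return AlignmentSet.from_records(records, lengths)


@dataclass
class MultimappingExperiment:
    """Inputs and intermediate products of the controlled design."""

    truth: CommunityTruth
    references: dict[str, str]
    alignments: AlignmentSet  # accepted (per-query near-best) alignments
    raw_alignments: AlignmentSet
    result: FamliResult

    @property
    def mean_candidates_per_read(self) -> float:
        per_query: dict[str, int] = {}
        for rec in self.alignments.records:
            per_query[rec.query_id] = per_query.get(rec.query_id, 0) + 1
        return sum(per_query.values()) / len(per_query)

    @property
    def fraction_correct(self) -> float:
        """Fraction of assigned reads whose subject equals their origin."""
        if not self.result.assignments:
            return 0.0
        good = sum(
            1
            for qid, sid in self.result.assignments.items()
            if self.truth.read_origin.get(qid) == sid
        )
        return good / len(self.result.assignments)

    @property
    def fraction_reads_correct(self) -> float:
        """Fraction of all simulated reads assigned to their true origin."""
        total = len(self.truth.read_origin)
        good = sum(
            1
            for qid, origin in self.truth.read_origin.items()
            if self.result.assignments.get(qid) == origin
        )
        return good / total if total else 0.0


def multimapping_experiment(
    seed: int = 1,
    *,
    n_cds: int = 3,
    reads_per_cds: int = 120,
    decoys_per_cds: int = 10,
    cds_length: int = 450,
    domain_fracs: tuple[float, ...] = (0.4, 0.6, 0.75),
    tolerance_pct: float = 10.0,
    params: FamliParams | None = None,
) -> MultimappingExperiment:
    """The controlled multi-mapping design: ``n_cds`` true CDS, each the
    first member of a homolog family whose remaining ``decoys_per_cds``
    members are reference-only decoys; ``reads_per_cds`` error-free pairs
    per CDS.  Domain sizes cycle through ``domain_fracs`` so some decoys die
    on coverage evenness and others only through iterative pruning."""
    truth = CommunityTruth()
    from .simulate import reverse_translate
    import numpy as np

    rng = np.random.default_rng(seed)
    for i in range(n_cds):
        frac = domain_fracs[i % len(domain_fracs)]
        domain_len = int(round(frac * cds_length))
        fam = make_homolog_family(
            1 + decoys_per_cds,
            domain_len,
            cds_length - domain_len,
            seed=int(rng.integers(2**31)),
            prefix=f"cds{i:02d}",
        )
        members = list(fam.items())
        cds_id, peptide = members[0]
        truth.cds_peptides[cds_id] = peptide
        truth.cds_nt[cds_id] = reverse_translate(peptide, rng)
        truth.cds_depths[cds_id] = float(
            reads_per_cds * 2 * 250 / (3 * cds_length)
        )
        for did, dseq in members[1:]:
            truth.decoy_peptides[did] = dseq

    # within-CDS fragments must tile the template rather than straddle it
    # end to end, so the fragment length is scaled to the CDS size here
    # (the whole-genome path keeps the standard 1 kb +/- 300 geometry)
    reads = simulate_reads(
        truth,
        SimParams(seed=seed, frag_mean=500.0, frag_sd=150.0),
        reads_per_cds=reads_per_cds,
        seed=int(rng.integers(2**31)),
    )
    references = truth.reference_peptides
    table = emulate_translated_alignment(reads, references)
    raw = alignment_table_to_set(table)
    accepted = accept_best(raw, tolerance_pct)
    result = run_famli(accepted, params or FamliParams())
    return MultimappingExperiment(
        truth=truth,
        references=references,
        alignments=accepted,
        raw_alignments=raw,
        result=result,
    )


@dataclass
class CommunityBenchmark:
    truth: CommunityTruth
    alignments: AlignmentSet
    famli_result: FamliResult
    detected: dict[str, set[str]] = field(default_factory=dict)
    metrics: dict[str, MetricReport] = field(default_factory=dict)


def detected_by_all_hits(alignments: AlignmentSet) -> set[str]:
    """Baseline: any reference with at least one accepted alignment."""
    return set(alignments.subject_ids)


def detected_by_unique_hits(alignments: AlignmentSet) -> set[str]:
    """Baseline: references with at least one read whose accepted candidate
    set is that single reference."""
    per_query: dict[str, set[str]] = {}
    for rec in alignments.records:
        per_query.setdefault(rec.query_id, set()).add(rec.subject_id)
    return {
        next(iter(subjects))
        for subjects in per_query.values()
        if len(subjects) == 1
    }


def evaluate_detected(
    detected_ids: set[str],
    references: dict[str, str],
    truth: CommunityTruth,
) -> MetricReport:
    """Cluster detected and true peptide sets at 90% identity, classify the
    detected representatives, and compute the detection metrics."""
    truth_reps, _ = cluster_90(truth.cds_peptides)
    depths_by_rep = {
        rep: truth.cds_depths[rep] for rep in truth_reps
    }
    if not detected_ids:
        labels = classify_detections({}, truth_reps)
        return compute_metrics(labels, depths_by_rep)
    det_seqs = {sid: references[sid] for sid in detected_ids}
    det_reps, _ = cluster_90(det_seqs)
    labels = classify_detections(det_reps, truth_reps)
    return compute_metrics(labels, depths_by_rep)


def community_benchmark(
    seed: int = 1,
    *,
    sim_params: SimParams | None = None,
    famli_params: FamliParams | None = None,
    tolerance_pct: float = 10.0,
    **community_kwargs,
) -> CommunityBenchmark:
    """Simulate one community, align its reads, and score the iterative
    filter against the all-hits and unique-hits mapping baselines."""
    sim_params = sim_params or SimParams(seed=seed)
    truth = make_community(sim_params, seed=seed, **community_kwargs)
    reads = simulate_reads(truth, sim_params, seed=seed + 1)
    references = truth.reference_peptides
    table = emulate_translated_alignment(reads, references)
    alignments = accept_best(alignment_table_to_set(table), tolerance_pct)
    result = run_famli(alignments, famli_params or FamliParams())

    bench = CommunityBenchmark(
        truth=truth, alignments=alignments, famli_result=result
    )
    bench.detected["famli"] = set(result.retained_subjects)
    bench.detected["all_hits"] = detected_by_all_hits(alignments)
    bench.detected["unique_hits"] = detected_by_unique_hits(alignments)
    for name, ids in bench.detected.items():
        bench.metrics[name] = evaluate_detected(ids, references, truth)
    return bench
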