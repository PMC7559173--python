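"""The iterative likelihood model that resolves multi-mapped reads.

Each query read starts with a candidate set of reference peptides (subjects)
it aligned to.  The model maintains a sparse per-(query, subject) score,
interpretable as the probability that the read originated from that subject:

1. scores are initialised from alignment bitscores, normalised to sum to 1
   per query;
2. each iteration, scores are weighted by the sample-wide evidence for the
   subject (the sum of that subject's scores over *all* queries), renormalised
   per query, and candidates falling below a fixed fraction of the query's
   best score are pruned;
3. iteration stops when nothing is pruned or a maximum is reached, each query
   is assigned to its single best surviving subject, and the coverage-evenness
   filter is re-applied to the deduplicated (one subject per read) alignments.

Subjects with genuinely even, deep coverage therefore accumulate weight and
absorb ambiguous reads, while domain-only decoys starve and are culled --
an expectation-maximisation-style fixed point reached in a handful of
iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment_io import AlignmentRecord, AlignmentSet
from .coverage import CoverageVector, compute_coverage, evenness_filter

logger = logging.getLogger(__name__)

_NORMALIZATION_TOL = 1e-9


class ScoreMatrix:
    """Sparse per-(query, subject) scores, normalised to sum to 1 per query.

    Stored as parallel arrays (query index, subject index, score) over interned
    id tables, which keeps the per-iteration updates pure numpy.
    """

    __slots__ = ("queries", "subjects", "q", "s", "scores", "_index")

    def __init__(
        self,
        queries: list[str],
        subjects: list[str],
        q: np.ndarray,
        s: np.ndarray,
        scores: np.ndarray,
    ) -> None:
        self.queries = queries
        self.subjects = subjects
        self.q = q
        self.s = s
        self.scores = scores
        self._index: dict[tuple[str, str], int] | None = None

    # -- construction --------------------------------------------------

    @classmethod
    def from_dict(cls, scores: dict[tuple[str, str], float]) -> "ScoreMatrix":
        queries: list[str] = []
        subjects: list[str] = []
        qmap: dict[str, int] = {}
        smap: dict[str, int] = {}
        q_idx, s_idx, vals = [], [], []
        for (qid, sid), val in scores.items():
            if qid not in qmap:
                qmap[qid] = len(queries)
                queries.append(qid)
            if sid not in smap:
                smap[sid] = len(subjects)
                subjects.append(sid)
            q_idx.append(qmap[qid])
            s_idx.append(smap[sid])
            vals.append(val)
        return cls(
            queries,
            subjects,
            np.asarray(q_idx, dtype=np.intp),
            np.asarray(s_idx, dtype=np.intp),
            np.asarray(vals, dtype=np.float64),
        )

    def _replace(self, q: np.ndarray, s: np.ndarray, scores: np.ndarray) -> "ScoreMatrix":
        return ScoreMatrix(self.queries, self.subjects, q, s, scores)

    # -- views ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.scores)

    def to_dict(self) -> dict[tuple[str, str], float]:
        return {
            (self.queries[qi], self.subjects[si]): float(v)
            for qi, si, v in zip(self.q, self.s, self.scores)
        }

    def get(self, query_id: str, subject_id: str) -> float | None:
        if self._index is None:
            self._index = {
                (self.queries[qi], self.subjects[si]): i
                for i, (qi, si) in enumerate(zip(self.q, self.s))
            }
        i = self._index.get((query_id, subject_id))
        return None if i is None else float(self.scores[i])

    def query_sums(self) -> np.ndarray:
        return np.bincount(
            self.q, weights=self.scores, minlength=len(self.queries)
        )

    def subject_weights(self) -> np.ndarray:
        """W(s): total score mass each subject holds across all queries."""
        return np.bincount(
            self.s, weights=self.scores, minlength=len(self.subjects)
        )

    def candidates_per_query(self) -> np.ndarray:
        return np.bincount(self.q, minlength=len(self.queries))

    def assert_normalized(self, tol: float = _NORMALIZATION_TOL) -> None:
        sums = self.query_sums()
        active = np.bincount(self.q, minlength=len(self.queries)) > 0
        if not np.allclose(sums[active], 1.0, atol=tol, rtol=0):
            worst = float(np.abs(sums[active] - 1.0).max())
            raise AssertionError(f"per-query score sums deviate by {worst:.3g}")


@dataclass
class FamliParams:
    """Tunables of the iterative filter.

    evenness_threshold:
        Maximum allowed coverage CV (CD_STD / CD_Mean); references above it
        are discarded both before scoring and at the final re-check.
    prune_ratio:
        A candidate is pruned when its score falls below ``prune_ratio`` times
        the best score of its query.  The per-query maximum always survives.
    max_iterations:
        Upper bound on reweight/prune rounds; iteration also stops as soon as
        a round prunes nothing.
    """

    evenness_threshold: float = 1.0
    prune_ratio: float = 0.5
    max_iterations: int = 10
    acceptance_metric: str = "identity"
    weighted_first_filter: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.prune_ratio <= 1:
            raise ValueError(f"prune_ratio must be in (0, 1], got {self.prune_ratio}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.evenness_threshold <= 0:
            raise ValueError("evenness_threshold must be > 0")


@dataclass
class FamliResult:
    """Outcome of a full run: one subject per surviving query."""

    assignments: dict[str, str] = field(default_factory=dict)
    retained_subjects: set[str] = field(default_factory=set)
    iterations_run: int = 0
    candidate_counts: list[int] = field(default_factory=list)
    n_unassigned: int = 0
    final_coverage: dict[str, CoverageVector] = field(default_factory=dict)
    subject_lengths: dict[str, int] = field(default_factory=dict)


def init_scores(alignments: AlignmentSet) -> ScoreMatrix:
    """Initial score(q, s) = bitscore(q, s) / sum of q's bitscores."""
    if len(alignments) == 0:
        raise ValueError("cannot initialise scores from an empty alignment set")
    queries: list[str] = []
    subjects: list[str] = []
    qmap: dict[str, int] = {}
    smap: dict[str, int] = {}
    q_idx = np.empty(len(alignments), dtype=np.intp)
    s_idx = np.empty(len(alignments), dtype=np.intp)
    bits = np.empty(len(alignments), dtype=np.float64)
    for i, rec in enumerate(alignments.records):
        qi = qmap.setdefault(rec.query_id, len(queries))
        if qi == len(queries):
            queries.append(rec.query_id)
        si = smap.setdefault(rec.subject_id, len(subjects))
        if si == len(subjects):
            subjects.append(rec.subject_id)
        q_idx[i] = qi
        s_idx[i] = si
        bits[i] = rec.bitscore

    sums = np.bincount(q_idx, weights=bits, minlength=len(queries))
    if np.any(sums <= 0):
        bad = queries[int(np.argmax(sums <= 0))]
        raise ValueError(f"query {bad!r} has zero total bitscore")
    return ScoreMatrix(queries, subjects, q_idx, s_idx, bits / sums[q_idx])


def reweight_and_renormalize(scores: ScoreMatrix) -> ScoreMatrix:
    """One E-step: scale each score by its subject's sample-wide weight
    W(s) = sum over queries of score(q, s), then renormalise per query."""
    weights = scores.subject_weights()
    raw = scores.scores * weights[scores.s]
    sums = np.bincount(scores.q, weights=raw, minlength=len(scores.queries))
    return scores._replace(scores.q, scores.s, raw / sums[scores.q])


def prune(scores: ScoreMatrix, prune_ratio: float) -> tuple[ScoreMatrix, int]:
    """Drop candidates scoring below ``prune_ratio`` x their query's maximum.

    Ties at the maximum all survive; the maximum itself always does.  The
    surviving scores are renormalised per query.
    """
    maxima = np.zeros(len(scores.queries))
    np.maximum.at(maxima, scores.q, scores.scores)
    keep = scores.scores >= prune_ratio * maxima[scores.q]
    n_pruned = int((~keep).sum())
    if n_pruned == 0:
        return scores, 0
    q, s, vals = scores.q[keep], scores.s[keep], scores.scores[keep]
    sums = np.bincount(q, weights=vals, minlength=len(scores.queries))
    return scores._replace(q, s, vals / sums[q]), n_pruned


def _final_assignments(scores: ScoreMatrix) -> dict[str, str]:
    """One subject per query: highest score, ties broken by higher subject
    weight W(s), then lexicographically smallest subject id."""
    weights = scores.subject_weights()
    name_rank = np.empty(len(scores.subjects), dtype=np.intp)
    name_rank[np.argsort(np.asarray(scores.subjects, dtype=object))] = np.arange(
        len(scores.subjects)
    )
    order = np.lexsort(
        (
            name_rank[scores.s],
            -weights[scores.s],
            -scores.scores,
            scores.q,
        )
    )
    assignments: dict[str, str] = {}
    seen: set[int] = set()
    for i in order:
        qi = int(scores.q[i])
        if qi not in seen:
            seen.add(qi)
            assignments[scores.queries[qi]] = scores.subjects[int(scores.s[i])]
    return assignments


def run_famli(
    alignments: AlignmentSet,
    params: FamliParams | None = None,
) -> FamliResult:
    """Full pipeline: evenness pre-filter, iterative reweight/prune, final
    per-query assignment, and the evenness re-check on the deduplicated
    one-subject-per-read alignments.

    Queries whose every candidate is removed by a coverage filter are counted
    in ``n_unassigned`` rather than silently dropped.  The run is fully
    deterministic.
    """
    params = params or FamliParams()
    result = FamliResult(subject_lengths=dict(alignments.subject_lengths))
    if len(alignments) == 0:
        return result

    all_queries = set(alignments.query_ids)

    # pass 1: unweighted coverage evenness (optionally bitscore-weighted)
    first_weights = None
    if params.weighted_first_filter:
        first_weights = init_scores(alignments)
    cov = compute_coverage(alignments, weights=first_weights)
    retained = evenness_filter(cov, params.evenness_threshold)
    logger.info(
        "evenness pre-filter: %d/%d subjects retained", len(retained), len(cov)
    )
    surviving = [r for r in alignments.records if r.subject_id in retained]
    if not surviving:
        logger.warning("all subjects removed by the evenness filter")
        result.n_unassigned = len(all_queries)
        return result
    working = alignments.subset(surviving)
    result.n_unassigned = len(all_queries) - len(set(working.query_ids))

    scores = init_scores(working)
    result.candidate_counts.append(len(scores))
    for _ in range(params.max_iterations):
        scores = reweight_and_renormalize(scores)
        scores, n_pruned = prune(scores, params.prune_ratio)
        result.iterations_run += 1
        result.candidate_counts.append(len(scores))
        logger.debug(
            "iteration %d: %d candidates remain (%d pruned)",
            result.iterations_run, len(scores), n_pruned,
        )
        if n_pruned == 0:
            break

    assignments = _final_assignments(scores)

    # deduplicated alignments: the single surviving record per query
    by_pair = {
        (rec.query_id, rec.subject_id): rec for rec in working.records
    }
    dedup_records = [
        by_pair[(qid, sid)] for qid, sid in assignments.items()
    ]
    dedup = working.subset(dedup_records)

    # pass 2: re-apply the evenness filter on unit-weight deduplicated coverage
    final_cov = compute_coverage(dedup)
    final_retained = evenness_filter(final_cov, params.evenness_threshold)
    dropped = {
        qid for qid, sid in assignments.items() if sid not in final_retained
    }
    if dropped:
        logger.info(
            "%d reads unassigned after the final evenness re-check", len(dropped)
        )
    result.n_unassigned += len(dropped)
    result.assignments = {
        qid: sid for qid, sid in assignments.items() if sid in final_retained
    }
    result.retained_subjects = set(result.assignments.values())
    result.final_coverage = {
        sid: vec for sid, vec in final_cov.items()
        if sid in result.retained_subjects
    }
    return result


SUMMARY_COLUMNS = ["id", "length", "nreads", "depth_mean", "depth_sd", "coverage_fraction"]


def summarize(
    result: FamliResult,
    coverage: dict[str, CoverageVector] | None = None,
) -> pd.DataFrame:
    """Per-retained-subject detection table.

    Columns: subject id, length (aa), number of assigned reads, mean and SD
    of the final deduplicated coverage depth, and the fraction of positions
    covered by at least one read.  Rows are sorted by subject id.
    """
    coverage = coverage if coverage is not None else result.final_coverage
    nreads: dict[str, int] = {}
    for sid in result.assignments.values():
        nreads[sid] = nreads.get(sid, 0) + 1
    rows = []
    for sid in sorted(result.retained_subjects):
        vec = coverage[sid]
        rows.append(
            {
                "id": sid,
                "length": len(vec.depth),
                "nreads": nreads.get(sid, 0),
                "depth_mean": vec.mean_depth,
                "depth_sd": vec.sd_depth,
                "coverage_fraction": vec.covered_fraction,
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
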