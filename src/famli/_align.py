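"""Seeded local protein alignment used by the emulated aligner and the
evaluation harness.

A k-mer seed index narrows each query to references it plausibly aligns to;
candidates are then scored with a Smith-Waterman alignment (BLOSUM62,
gap open -11 / extend -1, the blastp defaults) and raw scores converted to
bitscores with the standard Karlin-Altschul parameters for that scoring
system (lambda = 0.267, K = 0.041).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices

_LAMBDA = 0.267
_K = 0.041
_LN2 = math.log(2.0)


def make_protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="local", open_gap_score=-11.0, extend_gap_score=-1.0
    )
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    return aligner


def bitscore(raw_score: float) -> float:
    """Karlin-Altschul bit conversion: (lambda*S - ln K) / ln 2."""
    return (_LAMBDA * raw_score - math.log(_K)) / _LN2


def evalue(raw_score: float, query_len: int, subject_len: int) -> float:
    """Karlin-Altschul expect value, floored to avoid exact zero."""
    e = _K * query_len * subject_len * math.exp(-_LAMBDA * raw_score)
    return max(e, 1e-180)


class SeedIndex:
    """Exact k-mer index over a set of peptides (default k=6).

    Unrelated random peptides essentially never share a 6-mer, so the index
    both accelerates all-vs-all comparison and suppresses spurious hits.
    """

    def __init__(self, peptides: Mapping[str, str], k: int = 6) -> None:
        self.k = k
        self.peptides = dict(peptides)
        self._index: dict[str, list[str]] = {}
        for sid, seq in self.peptides.items():
            seen: set[str] = set()
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer not in seen:
                    seen.add(kmer)
                    self._index.setdefault(kmer, []).append(sid)

    def candidates(self, query: str) -> list[str]:
        """Reference ids sharing at least one k-mer with ``query``, in a
        deterministic (first-seen) order."""
        hits: dict[str, None] = {}
        for i in range(len(query) - self.k + 1):
            for sid in self._index.get(query[i : i + self.k], ()):
                hits.setdefault(sid, None)
        return list(hits)


@dataclass
class LocalHit:
    """A local alignment of a (peptide) query against a reference peptide.

    Coordinates are 1-based inclusive.  ``length`` is the number of alignment
    columns; ``identity`` is identities / columns.
    """

    subject_id: str
    raw_score: float
    bits: float
    length: int
    identities: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int

    @property
    def identity(self) -> float:
        return self.identities / self.length if self.length else 0.0


def align_local(
    aligner: Align.PairwiseAligner, query: str, subject_id: str, subject: str
) -> LocalHit | None:
    """Best local alignment of ``query`` vs ``subject``; None when the
    optimal score is not positive."""
    if not query or not subject:
        return None
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    counts = aln.counts()
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    n_columns = counts.identities + counts.mismatches + counts.gaps
    return LocalHit(
        subject_id=subject_id,
        raw_score=float(aln.score),
        bits=bitscore(float(aln.score)),
        length=int(n_columns),
        identities=int(counts.identities),
        mismatches=int(counts.mismatches),
        gap_opens=int(
            counts.open_internal_insertions + counts.open_internal_deletions
        ),
        query_start=int(qblocks[0][0]) + 1,
        query_end=int(qblocks[-1][1]),
        subject_start=int(sblocks[0][0]) + 1,
        subject_end=int(sblocks[-1][1]),
    )


def best_hits(
    aligner: Align.PairwiseAligner,
    query: str,
    index: SeedIndex,
    *,
    min_bits: float = 0.0,
    min_length: int = 1,
) -> list[LocalHit]:
    """Align ``query`` against every seeded candidate, keeping hits above the
    bitscore and alignment-length floors."""
    hits = []
    for sid in index.candidates(query):
        hit = align_local(aligner, query, sid, index.peptides[sid])
        if hit is not None and hit.bits >= min_bits and hit.length >= min_length:
            hits.append(hit)
    return hits
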