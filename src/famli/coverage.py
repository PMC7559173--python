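"""Per-reference amino-acid coverage and the coverage-evenness filter.

A reference peptide that is genuinely present in a sample recruits reads
roughly uniformly along its length, whereas a reference recruited only
through a shared conserved domain shows a sharp pile-up over the domain and
nothing elsewhere.  The evenness filter formalises this: a reference is
discarded when the coefficient of variation of its per-position coverage
depth, CD_STD / CD_Mean, exceeds a threshold (default 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .alignment_io import AlignmentSet

if TYPE_CHECKING:  # pragma: no cover
    from .core import ScoreMatrix


@dataclass
class CoverageVector:
    """Coverage depth (CD) at every amino-acid position of one reference.

    ``depth[i]`` is the number of reads (or, in the weighted phase, the sum of
    read -> subject scores) overlapping position ``i+1``.  Mean and standard
    deviation are taken over the *full* reference length, zeros included, and
    the SD is the population SD: the vector is the complete coverage profile,
    not a sample from it.
    """

    subject_id: str
    depth: np.ndarray

    @property
    def mean_depth(self) -> float:
        return float(np.mean(self.depth))

    @property
    def sd_depth(self) -> float:
        return float(np.std(self.depth))

    @property
    def cv(self) -> float:
        """CD_STD / CD_Mean; infinite for an all-zero vector."""
        mean = self.mean_depth
        if mean == 0.0:
            return float("inf")
        return self.sd_depth / mean

    @property
    def covered_fraction(self) -> float:
        return float(np.count_nonzero(self.depth)) / len(self.depth)


def compute_coverage(
    alignments: AlignmentSet,
    weights: "ScoreMatrix | None" = None,
) -> dict[str, CoverageVector]:
    """Overlay alignments into per-subject coverage vectors.

    Each aligned read adds 1 -- or its pair's current query->subject score
    when a weight matrix from the iterative phase is supplied -- to every
    position in its subject interval [sstart, send]; a record that collapsed
    the two mates of a pair contributes both mates' intervals.  Pairs absent
    from ``weights`` (i.e. already pruned) contribute nothing.  Subjects
    with no contributing alignment are absent from the result.
    """
    # difference-array accumulation: O(alignments + total subject length)
    diffs: dict[str, np.ndarray] = {}
    lengths = alignments.subject_lengths
    for rec in alignments.records:
        if weights is not None:
            w = weights.get(rec.query_id, rec.subject_id)
            if w is None or w == 0.0:
                continue
        else:
            w = 1.0
        length = lengths[rec.subject_id]
        diff = diffs.get(rec.subject_id)
        if diff is None:
            diff = np.zeros(length + 1)
            diffs[rec.subject_id] = diff
        for start, end in rec.all_intervals:
            if end > length:
                raise ValueError(
                    f"alignment {rec.query_id} vs {rec.subject_id} extends to "
                    f"{end} on a {length} aa subject"
                )
            diff[start - 1] += w
            diff[end] -= w

    return {
        sid: CoverageVector(sid, np.cumsum(diff[:-1]))
        for sid, diff in diffs.items()
    }


def evenness_filter(
    coverage: Mapping[str, CoverageVector],
    threshold: float = 1.0,
) -> set[str]:
    """Subjects whose coverage is even enough to keep.

    A subject is retained iff CD_STD / CD_Mean <= threshold; the filter fires
    only on strictly uneven coverage (CV exactly at the threshold is kept).
    Subjects with zero mean depth are always filtered.  CV is scale-free, so
    the decision is invariant under uniform scaling of the vector.
    """
    if threshold <= 0:
        raise ValueError(f"evenness threshold must be > 0, got {threshold}")
    return {
        sid for sid, vec in coverage.items() if vec.cv <= threshold
    }


def coverage_to_table(coverage: Mapping[str, CoverageVector]):
    """Per-position long-form table (subject, position, depth) for debugging."""
    import pandas as pd

    frames = [
        pd.DataFrame(
            {
                "subject": vec.subject_id,
                "position": np.arange(1, len(vec.depth) + 1),
                "depth": vec.depth,
            }
        )
        for vec in coverage.values()
    ]
    if not frames:
        return pd.DataFrame(columns=["subject", "position", "depth"])
    return pd.concat(frames, ignore_index=True)
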