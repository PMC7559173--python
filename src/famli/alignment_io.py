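"""Reading, validation and acceptance filtering of translated-alignment tables.

Translated aligners (blastx, DIAMOND) report one row per local alignment in a
12-column tab-separated format::

    qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore

with an optional 13th column carrying the subject (reference peptide) length
in amino acids.  This module parses that format into :class:`AlignmentSet`,
normalises it (mate suffixes stripped, one row per query/subject pair,
subject coordinates ordered), and applies the per-query acceptance rules used
to decide which near-best alignments a read is allowed to keep.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Standard blastx tabular column order; ``slen`` is the optional 13th column.
DEFAULT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "slen",
)

_MATE_SUFFIX = re.compile(r"(/[12]|[ _][12]:[A-Z0-9:+]*)$")


class AlignmentFormatError(ValueError):
    """Raised when an alignment table cannot be parsed or validated."""


def strip_mate_suffix(query_id: str) -> str:
    """Remove mate-pair decorations (``/1``, ``/2``, `` 1:N:0:...``) so the
    two mates of a read pair share a single query identity."""
    return _MATE_SUFFIX.sub("", query_id)


@dataclass(frozen=True)
class AlignmentRecord:
    """One query -> subject translated alignment.

    Subject coordinates are 1-based inclusive amino-acid positions on the
    reference peptide.  ``bitscore`` is the log-scaled alignment score used to
    weight candidate assignments.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    align_length: int
    subject_start: int
    subject_end: int
    bitscore: float
    evalue: float = 0.0
    mismatches: int = 0
    gap_opens: int = 0
    query_start: int = 1
    query_end: int = 0
    #: subject intervals of every read (mate) collapsed into this candidacy;
    #: empty means just [subject_start, subject_end].  Coverage counts reads
    #: per position, while the pair holds a single score.
    coverage_intervals: tuple[tuple[int, int], ...] = ()

    @property
    def all_intervals(self) -> tuple[tuple[int, int], ...]:
        return self.coverage_intervals or ((self.subject_start, self.subject_end),)

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent identity {self.percent_identity} outside [0, 100] "
                f"for {self.query_id} vs {self.subject_id}"
            )
        if self.bitscore <= 0:
            raise ValueError(
                f"non-positive bitscore {self.bitscore} for "
                f"{self.query_id} vs {self.subject_id}"
            )


@dataclass
class AlignmentSet:
    """A validated collection of alignments plus subject lengths (aa).

    Invariants enforced at construction:

    * every aligned subject has a known length and no alignment extends past it
    * subject_start <= subject_end (reversed pairs are swapped with a warning)
    * at most one record per (query, subject) pair -- when an aligner reports
      multiple local alignments for the same pair only the highest-bitscore
      one is kept, since the model tracks one candidacy per pair
    """

    records: list[AlignmentRecord] = field(default_factory=list)
    subject_lengths: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        records: Iterable[AlignmentRecord],
        subject_lengths: Mapping[str, int],
        *,
        strip_mates: bool = True,
        deduplicate: bool = True,
    ) -> "AlignmentSet":
        lengths = dict(subject_lengths)
        cleaned: list[AlignmentRecord] = []
        for rec in records:
            if strip_mates:
                stripped = strip_mate_suffix(rec.query_id)
                if stripped != rec.query_id:
                    rec = replace(rec, query_id=stripped)
            if rec.subject_start > rec.subject_end:
                logger.warning(
                    "swapping reversed subject coordinates %d-%d for %s vs %s",
                    rec.subject_start, rec.subject_end, rec.query_id, rec.subject_id,
                )
                rec = replace(
                    rec, subject_start=rec.subject_end, subject_end=rec.subject_start
                )
            if rec.subject_id not in lengths:
                raise AlignmentFormatError(
                    f"no subject length available for {rec.subject_id!r}; supply a "
                    "13-column table or a reference FASTA covering all subjects"
                )
            if rec.subject_end > lengths[rec.subject_id]:
                raise AlignmentFormatError(
                    f"alignment {rec.query_id} vs {rec.subject_id} ends at "
                    f"{rec.subject_end} but subject is only "
                    f"{lengths[rec.subject_id]} aa long"
                )
            cleaned.append(rec)

        if deduplicate:
            # One candidacy per (query, subject): the highest-bitscore row
            # carries the score, but every collapsed row (typically the two
            # mates of a pair) keeps its subject interval for coverage --
            # coverage counts reads per position, not candidacies.  Exact
            # bitscore ties are broken by a CRC of the row so the winner is
            # deterministic without systematically favouring mate 1.
            best: dict[tuple[str, str], tuple[float, int, AlignmentRecord]] = {}
            intervals: dict[tuple[str, str], dict[tuple[int, int], None]] = {}
            order: list[tuple[str, str]] = []
            for rec in cleaned:
                key = (rec.query_id, rec.subject_id)
                tag = zlib.crc32(
                    f"{rec.query_id}|{rec.subject_id}|{rec.subject_start}|"
                    f"{rec.subject_end}|{rec.align_length}".encode()
                )
                rank = (rec.bitscore, tag)
                intervals.setdefault(key, {})[
                    (rec.subject_start, rec.subject_end)
                ] = None
                if key not in best:
                    best[key] = (*rank, rec)
                    order.append(key)
                elif rank > best[key][:2]:
                    best[key] = (*rank, rec)
            cleaned = [
                replace(best[key][2], coverage_intervals=tuple(intervals[key]))
                if len(intervals[key]) > 1
                else best[key][2]
                for key in order
            ]

        return cls(records=cleaned, subject_lengths=lengths)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def query_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.query_id, None)
        return list(seen)

    @property
    def subject_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.subject_id, None)
        return list(seen)

    def subset(self, keep: Iterable[AlignmentRecord]) -> "AlignmentSet":
        keep = list(keep)
        return AlignmentSet(records=keep, subject_lengths=self.subject_lengths)


def read_subject_lengths(fasta_path: str | Path) -> dict[str, int]:
    """Length (aa) of every peptide in a reference FASTA."""
    return {
        rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
    }


def read_tabular_alignments(
    path: str | Path,
    columns: Sequence[str] = DEFAULT_COLUMNS,
    *,
    ref_fasta: str | Path | None = None,
    strip_mates: bool = True,
    deduplicate: bool = True,
) -> AlignmentSet:
    """Parse a blastx-style tab-separated alignment table.

    Parameters
    ----------
    path:
        Tab-separated file, one alignment per line, ``#``-prefixed comment
        lines ignored.
    columns:
        Field names in file order.  The default is the standard 12-column
        blastx order plus optional ``slen`` (subject length, aa) as column 13.
    ref_fasta:
        Reference peptide FASTA used for subject lengths when the table has
        no ``slen`` column.

    Raises
    ------
    AlignmentFormatError
        On short lines, non-numeric fields (with 1-based line numbers), or a
        subject whose length cannot be determined.
    """
    columns = list(columns)
    required = [c for c in columns if c != "slen"]
    idx = {name: i for i, name in enumerate(columns)}
    min_fields = max(idx[name] for name in required) + 1
    slen_col = idx.get("slen")

    records: list[AlignmentRecord] = []
    lengths: dict[str, int] = {}
    problems: list[str] = []

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                problems.append(
                    f"line {lineno}: expected at least {min_fields} columns, "
                    f"found {len(fields)}"
                )
                continue
            try:
                rec = AlignmentRecord(
                    query_id=fields[idx["qseqid"]],
                    subject_id=fields[idx["sseqid"]],
                    percent_identity=float(fields[idx["pident"]]),
                    align_length=int(fields[idx["length"]]),
                    mismatches=int(fields[idx["mismatch"]]),
                    gap_opens=int(fields[idx["gapopen"]]),
                    query_start=int(fields[idx["qstart"]]),
                    query_end=int(fields[idx["qend"]]),
                    subject_start=int(fields[idx["sstart"]]),
                    subject_end=int(fields[idx["send"]]),
                    evalue=float(fields[idx["evalue"]]),
                    bitscore=float(fields[idx["bitscore"]]),
                )
            except ValueError as exc:
                problems.append(f"line {lineno}: {exc}")
                continue
            if slen_col is not None and len(fields) > slen_col:
                try:
                    slen = int(fields[slen_col])
                except ValueError:
                    problems.append(
                        f"line {lineno}: non-integer subject length "
                        f"{fields[slen_col]!r}"
                    )
                    continue
                prior = lengths.setdefault(rec.subject_id, slen)
                if prior != slen:
                    problems.append(
                        f"line {lineno}: conflicting lengths for "
                        f"{rec.subject_id} ({prior} vs {slen})"
                    )
                    continue
            records.append(rec)

    if problems:
        raise AlignmentFormatError(
            f"{path}: malformed alignment table:\n  " + "\n  ".join(problems)
        )

    if ref_fasta is not None:
        fasta_lengths = read_subject_lengths(ref_fasta)
        for sid, length in fasta_lengths.items():
            lengths.setdefault(sid, length)

    return AlignmentSet.from_records(
        records, lengths, strip_mates=strip_mates, deduplicate=deduplicate
    )


def write_tabular_alignments(alignments: AlignmentSet, path: str | Path) -> None:
    """Write the 13-column tab-separated form (round-trips with the reader)."""
    with open(path, "w") as out:
        for rec in alignments.records:
            out.write(
                "\t".join(
                    str(v)
                    for v in (
                        rec.query_id,
                        rec.subject_id,
                        f"{rec.percent_identity:.2f}",
                        rec.align_length,
                        rec.mismatches,
                        rec.gap_opens,
                        rec.query_start,
                        rec.query_end,
                        rec.subject_start,
                        rec.subject_end,
                        f"{rec.evalue:.2e}",
                        f"{rec.bitscore:.1f}",
                        alignments.subject_lengths[rec.subject_id],
                    )
                )
                + "\n"
            )


def accept_best(
    alignments: AlignmentSet,
    tolerance_pct: float = 0.0,
    *,
    metric: str = "identity",
) -> AlignmentSet:
    """Keep, per query, only alignments within ``tolerance_pct`` of its best.

    With ``metric="identity"`` (default) the band is additive on the percent
    identity scale: records with ``pident >= best_pident - tolerance_pct``
    survive, so ``tolerance_pct=0`` is the top-hit rule (ties at the best
    retained) and ``tolerance_pct=10`` the "top-10" rule.  With
    ``metric="bitscore"`` the band is relative: ``bitscore >= best * (1 -
    tolerance_pct/100)``.

    Input ordering is preserved and at least one record per query always
    survives (the best itself).
    """
    if tolerance_pct < 0:
        raise ValueError(f"tolerance_pct must be >= 0, got {tolerance_pct}")
    if metric not in ("identity", "bitscore"):
        raise ValueError(f"unknown acceptance metric {metric!r}")

    key = (
        (lambda r: r.percent_identity)
        if metric == "identity"
        else (lambda r: r.bitscore)
    )
    best: dict[str, float] = {}
    for rec in alignments.records:
        val = key(rec)
        if best.get(rec.query_id, -1.0) < val:
            best[rec.query_id] = val

    if metric == "identity":
        def keep(rec: AlignmentRecord) -> bool:
            return key(rec) >= best[rec.query_id] - tolerance_pct
    else:
        def keep(rec: AlignmentRecord) -> bool:
            return key(rec) >= best[rec.query_id] * (1.0 - tolerance_pct / 100.0)

    return alignments.subset(rec for rec in alignments.records if keep(rec))
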