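"""Synthetic communities, reads and emulated translated alignments.

Everything the pipeline consumes can be generated here with known ground
truth: microbial "genomes" carrying protein coding sequences (CDS), some of
which belong to homologous families sharing an identical conserved domain
(the structure that makes short reads genuinely multi-map), per-genome
sequencing depths drawn log-normally, paired-end shotgun reads, and a
blastx-style tabular alignment file produced by an internal translated
aligner.  All generators are deterministic functions of their seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._align import SeedIndex, align_local, evalue, make_protein_aligner

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# one representative codon set per amino acid (standard code); reverse
# translation picks among synonymous codons at random
_CODONS = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimParams:
    """Simulation settings.

    Defaults describe the study conditions: communities of 20 genomes with
    per-genome depth drawn from a log-normal (median 5x, SD of 1 log10 unit,
    capped at 100x), 250 bp paired-end reads from 1000 +/- 300 bp fragments,
    and error-free base calls unless ``error_rate`` is raised.
    """

    n_genomes: int = 20
    depth_mean: float = 5.0
    depth_sd: float = 1.0
    depth_max: float = 100.0
    read_length: int = 250
    frag_mean: float = 1000.0
    frag_sd: float = 300.0
    error_rate: float = 0.0
    seed: int = 0
    #: interpret depth_mean as the log-normal's median (10**mu); set False to
    #: treat it as the arithmetic mean of the underlying normal in log-space
    #: scaled differently -- both conventions collapse to the same thing here,
    #: the switch exists for mean-of-log10 = log10(depth_mean) vs
    #: mu = log10(depth_mean) - depth_sd**2 * ln(10) / 2 (median vs mean).
    depth_mean_is_median: bool = True

    def __post_init__(self) -> None:
        for name in ("depth_mean", "depth_max", "read_length", "frag_mean", "frag_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.depth_sd < 0 or self.error_rate < 0:
            raise ValueError("depth_sd and error_rate must be >= 0")
        if self.read_length > self.frag_mean:
            logger.warning(
                "read_length %d exceeds mean fragment length %.0f",
                self.read_length, self.frag_mean,
            )


@dataclass
class ReadPair:
    read_id: str
    seq1: str
    seq2: str


@dataclass
class CommunityTruth:
    """A simulated community with full ground truth.

    ``cds_peptides`` are the truly present proteins; ``decoy_peptides`` are
    homologs present in the reference database but absent from the community.
    ``read_origin`` maps each simulated read-pair id to the CDS it overlaps
    most (pairs overlapping no CDS by at least one codon carry no label).
    """

    genome_sequences: dict[str, str] = field(default_factory=dict)
    genome_depths: dict[str, float] = field(default_factory=dict)
    cds_peptides: dict[str, str] = field(default_factory=dict)
    cds_nt: dict[str, str] = field(default_factory=dict)
    cds_locations: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    cds_depths: dict[str, float] = field(default_factory=dict)
    decoy_peptides: dict[str, str] = field(default_factory=dict)
    read_origin: dict[str, str] = field(default_factory=dict)

    @property
    def reference_peptides(self) -> dict[str, str]:
        """The full reference database: true CDS plus decoy homologs."""
        refs = dict(self.cds_peptides)
        refs.update(self.decoy_peptides)
        return refs


# ---------------------------------------------------------------------------
# depth model


def sample_depths(
    n: int,
    params: SimParams | None = None,
    seed: int | None = None,
    ids: Iterable[str] | None = None,
) -> dict[str, float]:
    """Draw per-genome sequencing depths from the capped log-normal model:
    depth = min(depth_max, 10**N(log10(depth_mean), depth_sd))."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mu = math.log10(params.depth_mean)
    if not params.depth_mean_is_median:
        mu -= params.depth_sd**2 * math.log(10.0) / 2.0
    draws = 10.0 ** rng.normal(mu, params.depth_sd, size=n)
    depths = np.minimum(draws, params.depth_max)
    names = list(ids) if ids is not None else [f"g{i:03d}" for i in range(n)]
    if len(names) != n:
        raise ValueError("ids, when given, must have length n")
    return {name: float(d) for name, d in zip(names, depths)}


# ---------------------------------------------------------------------------
# sequences


def random_peptide(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def reverse_translate(peptide: str, rng: np.random.Generator, stop: bool = True) -> str:
    codons = [_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in peptide]
    if stop:
        codons.append("TAA")
    return "".join(codons)


def make_homolog_family(
    n_members: int,
    domain_length: int,
    unique_length: int,
    divergence: float = 0.1,
    seed: int = 0,
    prefix: str = "fam",
) -> dict[str, str]:
    """Peptides sharing an identical conserved domain with member-unique
    flanks.

    Each member is left-flank + domain + right-flank, where the domain block
    (``domain_length`` aa) is shared verbatim and the flanks
    (``unique_length`` aa total per member, split around the domain) are
    drawn independently per member, keeping pairwise flank identity at the
    random-alphabet baseline (~5%), i.e. at most ``divergence`` for any
    sensible setting.  Reads falling wholly inside the domain align equally
    to every member; reads reaching a flank do not.
    """
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    if divergence < 1.0 / len(AMINO_ACIDS):
        logger.warning(
            "divergence %.3f is below the random-alphabet identity baseline",
            divergence,
        )
    rng = np.random.default_rng(seed)
    domain = random_peptide(domain_length, rng)
    left_len = unique_length // 2
    right_len = unique_length - left_len
    family = {}
    for i in range(n_members):
        left = random_peptide(left_len, rng)
        right = random_peptide(right_len, rng)
        family[f"{prefix}_m{i}"] = left + domain + right
    return family


def make_community(
    params: SimParams | None = None,
    seed: int | None = None,
    *,
    cds_per_genome: int = 8,
    cds_length_range: tuple[int, int] = (150, 400),
    spacer_length: int = 150,
    p_twin: float = 0.25,
    p_domain_family: float = 0.25,
    twin_domain_frac: float = 0.9,
    family_domain_frac: float = 0.35,
    decoys_per_family: int = 2,
) -> CommunityTruth:
    """Build a community of genomes whose CDS content mixes three homology
    classes, mirroring the structure of real protein reference databases:

    * *twins* (probability ``p_twin``): the CDS has a near-full-length decoy
      homolog in the reference (shared domain ~90% of the length), so nearly
      every read from it multi-maps and no read maps uniquely;
    * *domain families* (``p_domain_family``): the CDS shares a conserved
      domain (~35% of its length) with ``decoys_per_family`` decoys, which
      recruit domain reads but show coverage only over the domain;
    * *singletons*: unrelated to everything else.

    Genomes are CDS separated by random intergenic spacers; per-genome depths
    come from :func:`sample_depths`.
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    truth = CommunityTruth()

    genome_ids = [f"g{i:03d}" for i in range(params.n_genomes)]
    truth.genome_depths = sample_depths(
        params.n_genomes, params, seed=int(rng.integers(2**31)), ids=genome_ids
    )

    for gid in genome_ids:
        parts = []
        pos = 0
        spacer = "".join(rng.choice(list("ACGT"), size=spacer_length))
        parts.append(spacer)
        pos += len(spacer)
        for j in range(cds_per_genome):
            cds_id = f"{gid}_cds{j:02d}"
            length = int(rng.integers(cds_length_range[0], cds_length_range[1] + 1))
            roll = rng.random()
            if roll < p_twin:
                domain_len = int(round(twin_domain_frac * length))
                fam = make_homolog_family(
                    2, domain_len, length - domain_len,
                    seed=int(rng.integers(2**31)), prefix=f"{cds_id}_twin",
                )
                members = list(fam.items())
                peptide = members[0][1]
                for did, dseq in members[1:]:
                    truth.decoy_peptides[did] = dseq
            elif roll < p_twin + p_domain_family:
                domain_len = int(round(family_domain_frac * length))
                fam = make_homolog_family(
                    1 + decoys_per_family, domain_len, length - domain_len,
                    seed=int(rng.integers(2**31)), prefix=f"{cds_id}_fam",
                )
                members = list(fam.items())
                peptide = members[0][1]
                for did, dseq in members[1:]:
                    truth.decoy_peptides[did] = dseq
            else:
                peptide = random_peptide(length, rng)
            nt = reverse_translate(peptide, rng)
            truth.cds_peptides[cds_id] = peptide
            truth.cds_nt[cds_id] = nt
            truth.cds_locations[cds_id] = (gid, pos, pos + len(nt))
            truth.cds_depths[cds_id] = truth.genome_depths[gid]
            parts.append(nt)
            pos += len(nt)
            spacer = "".join(rng.choice(list("ACGT"), size=spacer_length))
            parts.append(spacer)
            pos += len(spacer)
        truth.genome_sequences[gid] = "".join(parts)

    return truth


# ---------------------------------------------------------------------------
# reads


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def _simulate_from_template(
    template_id: str,
    template: str,
    n_pairs: int,
    params: SimParams,
    rng: np.random.Generator,
) -> list[ReadPair]:
    L = len(template)
    rl = params.read_length
    pairs = []
    for i in range(n_pairs):
        frag_len = int(round(rng.normal(params.frag_mean, params.frag_sd)))
        frag_len = max(rl, min(frag_len, L))
        start = int(rng.integers(0, L - frag_len + 1))
        frag = template[start : start + frag_len]
        seq1 = _mutate(frag[:rl], params.error_rate, rng)
        seq2 = _mutate(reverse_complement(frag[-rl:]), params.error_rate, rng)
        pairs.append(
            ReadPair(f"{template_id}_p{i:05d}|{start}|{frag_len}", seq1, seq2)
        )
    return pairs


def _label_origin(
    truth: CommunityTruth,
    gid: str,
    start: int,
    frag_len: int,
    read_length: int,
    cds_by_genome: dict[str, list[tuple[int, int, str]]],
) -> str | None:
    rl = read_length
    mate_ivals = [(start, start + rl), (start + frag_len - rl, start + frag_len)]
    if mate_ivals[1][0] < mate_ivals[0][1]:  # overlapping mates -> one interval
        mate_ivals = [(start, start + frag_len)]
    best_id, best_ov = None, 2  # require >= 3 nt (one codon) of overlap
    for cstart, cend, cid in cds_by_genome.get(gid, ()):
        ov = sum(
            max(0, min(cend, b) - max(cstart, a)) for a, b in mate_ivals
        )
        if ov > best_ov or (ov == best_ov and best_id is not None and cid < best_id):
            best_id, best_ov = cid, ov
    return best_id


def simulate_reads(
    truth: CommunityTruth,
    params: SimParams | None = None,
    *,
    reads_per_cds: int | None = None,
    seed: int | None = None,
) -> list[ReadPair]:
    """Simulate paired-end reads and record per-pair origin labels in
    ``truth.read_origin``.

    In the default (community) mode each genome yields
    ``round(depth * genome_length / (2 * read_length))`` pairs; fragment
    lengths are normal(frag_mean, frag_sd), truncated to [read_length,
    template length].  With ``reads_per_cds`` set, exactly that many pairs
    are drawn from every CDS nucleotide sequence instead (the controlled
    design used for studying multi-mapping directly).
    """
    params = params or SimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    reads: list[ReadPair] = []

    if reads_per_cds is not None:
        for cds_id in truth.cds_nt:
            pairs = _simulate_from_template(
                cds_id, truth.cds_nt[cds_id], reads_per_cds, params, rng
            )
            for pair in pairs:
                truth.read_origin[pair.read_id] = cds_id
            reads.extend(pairs)
        return reads

    cds_by_genome: dict[str, list[tuple[int, int, str]]] = {}
    for cid, (gid, cstart, cend) in truth.cds_locations.items():
        cds_by_genome.setdefault(gid, []).append((cstart, cend, cid))
    for gid in cds_by_genome:
        cds_by_genome[gid].sort()

    for gid, template in truth.genome_sequences.items():
        depth = truth.genome_depths[gid]
        n_pairs = int(round(depth * len(template) / (2.0 * params.read_length)))
        pairs = _simulate_from_template(gid, template, n_pairs, params, rng)
        for pair in pairs:
            _, start, frag_len = pair.read_id.rsplit("|", 2)
            origin = _label_origin(
                truth, gid, int(start), int(frag_len), params.read_length,
                cds_by_genome,
            )
            if origin is not None:
                truth.read_origin[pair.read_id] = origin
        reads.extend(pairs)
    return reads


# ---------------------------------------------------------------------------
# emulated translated aligner


def _translate(seq: str) -> str:
    from Bio.Seq import Seq

    usable = len(seq) - len(seq) % 3
    return str(Seq(seq[:usable]).translate())


def six_frame_segments(seq: str, min_len: int) -> list[tuple[str, int]]:
    """Stop-free peptide segments of all six reading frames, with the nt
    offset (on the aligning strand) where each segment starts."""
    segments = []
    for strand_seq in (seq, reverse_complement(seq)):
        for frame in range(3):
            aa = _translate(strand_seq[frame:])
            pos = 0
            for chunk in aa.split("*"):
                if len(chunk) >= min_len:
                    segments.append((chunk, frame + 3 * pos))
                pos += len(chunk) + 1
    return segments


def emulate_translated_alignment(
    reads: Iterable[ReadPair],
    references: Mapping[str, str],
    *,
    min_bits: float = 30.0,
    min_aln_len: int = 20,
    seed_k: int = 6,
) -> pd.DataFrame:
    """Align reads against reference peptides in translated (blastx-style)
    space and emit the standard 12-column tabular rows plus subject length.

    Every read mate is six-frame translated; stop-free segments are matched
    against a k-mer seed index of the references and candidates are scored by
    local alignment (BLOSUM62, gap -11/-1).  One row is emitted per
    (mate, reference): the best local alignment over all frames.  Because
    scoring is exact and deterministic, an error-free read's true origin is
    always among its best-scoring hits, and reads lying wholly inside a
    conserved domain receive identical bitscores for every family member.
    """
    references = dict(references)
    if not references:
        raise ValueError("empty reference set")
    index = SeedIndex(references, k=seed_k)
    aligner = make_protein_aligner()

    rows = []
    for pair in reads:
        for mate, seq in ((1, pair.seq1), (2, pair.seq2)):
            best: dict[str, tuple] = {}
            for segment, _offset in six_frame_segments(seq, min_len=seed_k):
                for sid in index.candidates(segment):
                    hit = align_local(aligner, segment, sid, references[sid])
                    if hit is None or hit.length < min_aln_len or hit.bits < min_bits:
                        continue
                    prev = best.get(sid)
                    if prev is None or hit.raw_score > prev[0].raw_score:
                        best[sid] = (hit, segment)
            for sid in sorted(best):
                hit, segment = best[sid]
                rows.append(
                    (
                        f"{pair.read_id}/{mate}",
                        sid,
                        round(100.0 * hit.identity, 2),
                        hit.length,
                        hit.mismatches,
                        hit.gap_opens,
                        hit.query_start,
                        hit.query_end,
                        hit.subject_start,
                        hit.subject_end,
                        evalue(hit.raw_score, len(segment), len(references[sid])),
                        round(hit.bits, 1),
                        len(references[sid]),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore", "slen",
        ],
    )


# ---------------------------------------------------------------------------
# file output


def write_fastq(reads: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> None:
    with open(path1, "w") as out1, open(path2, "w") as out2:
        for pair in reads:
            out1.write(f"@{pair.read_id}/1\n{pair.seq1}\n+\n{'I' * len(pair.seq1)}\n")
            out2.write(f"@{pair.read_id}/2\n{pair.seq2}\n+\n{'I' * len(pair.seq2)}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for sid, seq in sequences.items():
            out.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def write_alignments_tsv(table: pd.DataFrame, path: str | Path, header: str = "") -> None:
    with open(path, "w") as out:
        if header:
            out.write(header)
        table.to_csv(out, sep="\t", header=False, index=False)
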