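import numpy as np
import pytest

from famli.evaluation import global_identity
from famli.simulate import (
    CommunityTruth,
    ReadPair,
    SimParams,
    emulate_translated_alignment,
    make_community,
    make_homolog_family,
    random_peptide,
    reverse_complement,
    reverse_translate,
    sample_depths,
    simulate_reads,
)


class TestSampleDepths:
    def test_bounds_and_count(self):
        depths = sample_depths(20, SimParams(), seed=1)
        assert len(depths) == 20
        assert all(0 < d <= 100 for d in depths.values())

    def test_degenerate_sd_gives_exact_mean(self):
        depths = sample_depths(5, SimParams(depth_sd=0.0), seed=1)
        assert all(d == pytest.approx(5.0) for d in depths.values())

    def test_median_matches_lognormal_median(self):
        """The sample median estimates the log-normal median (5x) to within
        Monte-Carlo error: 3 standard errors of the median, which in log10
        space is 1.2533 * sd / sqrt(n)."""
        n = 10_000
        depths = np.array(list(sample_depths(n, SimParams(), seed=2).values()))
        se_log10 = 1.2533 * 1.0 / np.sqrt(n)
        assert abs(np.log10(np.median(depths)) - np.log10(5.0)) < 3 * se_log10
        assert depths.max() <= 100.0

    def test_deterministic_per_seed(self):
        assert sample_depths(10, seed=3) == sample_depths(10, seed=3)


class TestHomologFamily:
    def test_shared_domain_block(self):
        fam = make_homolog_family(2, 50, 50, seed=1)
        a, b = fam.values()
        assert len(a) == len(b) == 100
        assert a[25:75] == b[25:75]  # identical central domain
        assert a != b

    def test_zero_domain_members_dissimilar(self):
        fam = make_homolog_family(3, 0, 120, divergence=0.1, seed=2)
        seqs = list(fam.values())
        for i in range(3):
            for j in range(i + 1, 3):
                assert global_identity(seqs[i], seqs[j]) < 0.3

    def test_deterministic(self):
        assert make_homolog_family(4, 30, 40, seed=9) == make_homolog_family(
            4, 30, 40, seed=9
        )


def _controlled_truth(n_cds=3, length=300, seed=0):
    rng = np.random.default_rng(seed)
    truth = CommunityTruth()
    for i in range(n_cds):
        pep = random_peptide(length, rng)
        truth.cds_peptides[f"c{i}"] = pep
        truth.cds_nt[f"c{i}"] = reverse_translate(pep, rng)
    return truth


class TestSimulateReads:
    def test_forced_mode_exact_pair_count(self):
        truth = _controlled_truth(3)
        reads = simulate_reads(truth, SimParams(), reads_per_cds=120, seed=1)
        assert len(reads) == 360
        assert len(truth.read_origin) == 360
        per_cds = {}
        for rid, cid in truth.read_origin.items():
            per_cds[cid] = per_cds.get(cid, 0) + 1
        assert set(per_cds.values()) == {120}

    def test_error_free_reads_match_template(self):
        truth = _controlled_truth(1, length=500)
        reads = simulate_reads(truth, SimParams(), reads_per_cds=20, seed=2)
        template = truth.cds_nt["c0"]
        for pair in reads:
            _, start, frag = pair.read_id.rsplit("|", 2)
            start, frag = int(start), int(frag)
            assert pair.seq1 == template[start : start + 250]
            assert pair.seq2 == reverse_complement(
                template[start + frag - 250 : start + frag]
            )

    def test_pair_count_follows_depth_formula(self):
        truth = CommunityTruth()
        rng = np.random.default_rng(4)
        truth.genome_sequences["g"] = "".join(rng.choice(list("ACGT"), 30_000))
        truth.genome_depths["g"] = 10.0
        reads = simulate_reads(truth, SimParams(), seed=4)
        expected = 10.0 * 30_000 / (2 * 250)
        assert abs(len(reads) - expected) <= 0.05 * expected

    def test_substitution_errors_at_requested_rate(self):
        truth = _controlled_truth(1, length=500)
        params = SimParams(error_rate=0.02)
        reads = simulate_reads(truth, params, reads_per_cds=50, seed=5)
        template = truth.cds_nt["c0"]
        mismatches = bases = 0
        for pair in reads:
            _, start, frag = pair.read_id.rsplit("|", 2)
            ref = template[int(start) : int(start) + 250]
            mismatches += sum(a != b for a, b in zip(pair.seq1, ref))
            bases += len(ref)
        assert mismatches / bases == pytest.approx(0.02, rel=0.3)

    def test_community_origin_labels_point_to_overlapped_cds(self):
        params = SimParams(n_genomes=2, seed=7)
        truth = make_community(params, cds_per_genome=3)
        simulate_reads(truth, params, seed=8)
        assert truth.read_origin  # some pairs overlap a CDS
        for rid, cid in truth.read_origin.items():
            gid, cstart, cend = truth.cds_locations[cid]
            assert rid.startswith(gid)
            _, start, frag = rid.rsplit("|", 2)
            # the labelled CDS overlaps the fragment
            assert int(start) < cend and int(start) + int(frag) > cstart


class TestEmulatedAligner:
    def test_domain_read_hits_all_members_with_equal_bitscores(self):
        fam = make_homolog_family(5, 60, 60, seed=3)
        rng = np.random.default_rng(3)
        member = next(iter(fam.values()))
        # 27 aa wholly inside the 60-aa central domain -> 81 nt read
        domain_sub = member[32:59]
        nt = reverse_translate(domain_sub, rng, stop=False)
        pair = ReadPair("r0", nt, reverse_complement(nt))
        table = emulate_translated_alignment([pair], fam, min_aln_len=20)
        mate1 = table[table.qseqid == "r0/1"]
        assert set(mate1.sseqid) == set(fam)
        assert mate1.bitscore.nunique() == 1

    def test_unique_flank_read_hits_one_member(self):
        fam = make_homolog_family(5, 60, 80, seed=4)
        rng = np.random.default_rng(4)
        first_id, member = next(iter(fam.items()))
        flank_sub = member[2:36]  # inside the 40-aa left flank
        nt = reverse_translate(flank_sub, rng, stop=False)
        pair = ReadPair("r0", nt, reverse_complement(nt))
        table = emulate_translated_alignment([pair], fam, min_aln_len=20)
        assert set(table.sseqid) == {first_id}

    def test_unrelated_read_yields_no_rows(self):
        rng = np.random.default_rng(5)
        refs = {"ref": random_peptide(200, rng)}
        junk = reverse_translate(random_peptide(60, rng), rng, stop=False)
        pair = ReadPair("r0", junk, reverse_complement(junk))
        table = emulate_translated_alignment([pair], refs)
        assert table.empty

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            emulate_translated_alignment([], {})

    def test_true_origin_among_best_hits(self, mm_exp):
        """Every labelled read's top-bitscore hit set contains its origin."""
        best = {}
        for rec in mm_exp.raw_alignments.records:
            cur = best.setdefault(rec.query_id, [])
            cur.append((rec.bitscore, rec.subject_id))
        misses = 0
        for rid, origin in mm_exp.truth.read_origin.items():
            hits = best.get(rid)
            if hits is None:
                continue
            top = max(b for b, _ in hits)
            top_ids = {s for b, s in hits if b == top}
            misses += origin not in top_ids
        assert misses == 0


def test_community_generator_structure():
    params = SimParams(n_genomes=4, seed=11)
    truth = make_community(params, cds_per_genome=5)
    assert len(truth.cds_peptides) == 20
    assert set(truth.cds_depths.values()) <= set(truth.genome_depths.values())
    # CDS nucleotide sequences are embedded verbatim at their locations
    for cid, (gid, start, end) in truth.cds_locations.items():
        assert truth.genome_sequences[gid][start:end] == truth.cds_nt[cid]
    # decoys exist and are absent from every genome
    assert truth.decoy_peptides
    assert not set(truth.decoy_peptides) & set(truth.cds_peptides)


def test_generators_deterministic_per_seed():
    p = SimParams(n_genomes=3, seed=13)
    t1, t2 = make_community(p), make_community(p)
    assert t1.genome_sequences == t2.genome_sequences
    r1 = simulate_reads(t1, p, seed=14)
    r2 = simulate_reads(t2, p, seed=14)
    assert [(r.read_id, r.seq1, r.seq2) for r in r1] == [
        (r.read_id, r.seq1, r.seq2) for r in r2
    ]
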