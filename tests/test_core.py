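import itertools

import numpy as np
import pytest

from famli.core import (
    FamliParams,
    ScoreMatrix,
    init_scores,
    prune,
    reweight_and_renormalize,
    run_famli,
    summarize,
)

from conftest import make_set
from oracle import brute_init, brute_iterate

L = {"A": 100, "B": 100, "C": 100, "D": 100}


def full_cover_rows(pairs):
    """(query, subject, bitscore) rows spanning the whole subject, so the
    evenness filter is neutral and the score dynamics are isolated."""
    return [(q, s, 100.0, bits, 1, 100) for q, s, bits in pairs]


class TestInitScores:
    def test_single_candidate_is_certain(self):
        sm = init_scores(make_set(full_cover_rows([("q1", "A", 50.0)]), L))
        assert sm.get("q1", "A") == pytest.approx(1.0)

    def test_equal_bitscores_split_evenly(self):
        rows = full_cover_rows([("q1", "A", 40.0), ("q1", "B", 40.0)])
        sm = init_scores(make_set(rows, L))
        assert sm.get("q1", "A") == pytest.approx(0.5)

    def test_bitscore_proportionality(self):
        rows = full_cover_rows([("q1", "A", 60.0), ("q1", "B", 40.0)])
        sm = init_scores(make_set(rows, L))
        assert sm.get("q1", "A") == pytest.approx(0.6)
        assert sm.get("q1", "B") == pytest.approx(0.4)


class TestReweight:
    def test_shared_subject_pulls_score(self):
        """q2 is split between A and B; q1's unique alignment to A gives
        W(A)=1.5 vs W(B)=0.5, so q2 renormalises to 0.75 / 0.25."""
        sm = ScoreMatrix.from_dict(
            {("q1", "A"): 1.0, ("q2", "A"): 0.5, ("q2", "B"): 0.5}
        )
        out = reweight_and_renormalize(sm)
        assert out.get("q2", "A") == pytest.approx(0.75)
        assert out.get("q2", "B") == pytest.approx(0.25)
        assert out.get("q1", "A") == pytest.approx(1.0)

    def test_single_candidate_fixed_point(self):
        sm = ScoreMatrix.from_dict({("q1", "A"): 1.0})
        assert reweight_and_renormalize(sm).get("q1", "A") == pytest.approx(1.0)


class TestPrune:
    def test_below_relative_threshold_dropped(self):
        sm = ScoreMatrix.from_dict({("q1", "A"): 0.75, ("q1", "B"): 0.25})
        out, n = prune(sm, 0.5)
        assert n == 1
        assert out.get("q1", "A") == pytest.approx(1.0)
        assert out.get("q1", "B") is None

    def test_ties_at_max_survive(self):
        sm = ScoreMatrix.from_dict({("q1", "A"): 0.5, ("q1", "B"): 0.5})
        out, n = prune(sm, 1.0)
        assert n == 0 and len(out) == 2

    def test_single_candidate_untouched(self):
        sm = ScoreMatrix.from_dict({("q1", "A"): 1.0})
        out, n = prune(sm, 0.99)
        assert n == 0 and out.get("q1", "A") == pytest.approx(1.0)


def random_instance(rng, n_queries=6, n_subjects=5, density=0.5):
    scores = {}
    for qi in range(n_queries):
        subjects = [si for si in range(n_subjects) if rng.random() < density]
        if not subjects:
            subjects = [int(rng.integers(n_subjects))]
        for si in subjects:
            scores[(f"q{qi}", f"s{si}")] = float(rng.uniform(0.05, 100.0))
    return scores


def test_normalization_preserved_through_updates():
    """Per-query sums stay at 1 after init, reweight and prune."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        sm = ScoreMatrix.from_dict(brute_init(random_instance(rng)))
        for _ in range(3):
            sm = reweight_and_renormalize(sm)
            sm.assert_normalized()
            sm, _n = prune(sm, 0.5)
            sm.assert_normalized()


def test_oracle_equivalence_small_instances():
    """Array-based updates match the independent dict recurrence to 1e-12 on
    every support pattern of up to 3 queries x 3 subjects, bitscores cycling
    through a small grid."""
    grid = [10.0, 25.0, 40.0]
    subject_subsets = [
        tuple(c)
        for n in (1, 2, 3)
        for c in itertools.combinations(range(3), n)
    ]
    counter = 0
    for pattern in itertools.product(subject_subsets, repeat=3):
        bitscores = {}
        for qi, subjects in enumerate(pattern):
            for si in subjects:
                bitscores[(f"q{qi}", f"s{si}")] = grid[counter % len(grid)]
                counter += 1
        trajectory = brute_iterate(bitscores, ratio=0.5, max_iterations=10)

        sm = init_scores(
            make_set(
                full_cover_rows([(q, {"s0": "A", "s1": "B", "s2": "C"}[s], b)
                                 for (q, s), b in bitscores.items()]),
                L,
            )
        )
        back = {"A": "s0", "B": "s1", "C": "s2"}
        for step, expected in enumerate(trajectory):
            got = {
                (q, back[s]): v for (q, s), v in sm.to_dict().items()
            }
            assert got.keys() == expected.keys(), f"step {step}"
            for key, val in expected.items():
                assert got[key] == pytest.approx(val, abs=1e-12), f"step {step}"
            if step < len(trajectory) - 1:
                sm = reweight_and_renormalize(sm)
                sm, _ = prune(sm, 0.5)


def test_candidate_counts_monotone_and_unique_reads_safe():
    rng = np.random.default_rng(5)
    for _ in range(50):
        scores = brute_init(random_instance(rng))
        unique_queries = {
            q for q in {k[0] for k in scores}
            if sum(1 for k in scores if k[0] == q) == 1
        }
        sm = ScoreMatrix.from_dict(scores)
        prev = len(sm)
        for _ in range(10):
            sm = reweight_and_renormalize(sm)
            sm, n_pruned = prune(sm, 0.5)
            assert len(sm) <= prev
            prev = len(sm)
            present = {sm.queries[qi] for qi in sm.q}
            assert unique_queries <= present
            if n_pruned == 0:
                break


class TestRunFamli:
    def test_unique_mapping_is_identity(self):
        rows = full_cover_rows([("q1", "A", 50.0), ("q2", "B", 60.0)])
        result = run_famli(make_set(rows, L))
        assert result.assignments == {"q1": "A", "q2": "B"}
        assert result.iterations_run == 1  # first pass prunes nothing
        assert result.n_unassigned == 0

    def test_exact_symmetry_resolved_deterministically(self):
        """Two indistinguishable references: the documented tie-break
        (higher W, then lexicographically smallest id) picks one winner."""
        rows = full_cover_rows(
            [("q1", "A", 50.0), ("q1", "B", 50.0),
             ("q2", "A", 50.0), ("q2", "B", 50.0)]
        )
        result = run_famli(make_set(rows, L))
        assert set(result.assignments.values()) == {"A"}
        again = run_famli(make_set(rows, L))
        assert again.assignments == result.assignments

    def test_empty_input_gives_empty_result(self):
        result = run_famli(make_set([], L))
        assert result.assignments == {} and result.retained_subjects == set()

    def test_all_subjects_uneven_gives_empty_result_with_unassigned(self):
        rows = [("q1", "A", 100.0, 50.0, 1, 5)]  # 5/100 positions: CV >> 1
        result = run_famli(make_set(rows, L))
        assert result.assignments == {}
        assert result.n_unassigned == 1

    def test_deterministic_on_experiment(self, mm_exp):
        from famli.core import FamliParams
        again = run_famli(mm_exp.alignments, FamliParams())
        assert again.assignments == mm_exp.result.assignments
        assert again.candidate_counts == mm_exp.result.candidate_counts


class TestSummarize:
    def test_empty_report_has_header(self):
        from famli.core import FamliResult

        report = summarize(FamliResult())
        assert list(report.columns) == [
            "id", "length", "nreads", "depth_mean", "depth_sd",
            "coverage_fraction",
        ]
        assert report.empty

    def test_single_subject_overlay_consistency(self):
        """10 reads each covering a distinct 25-aa quarter-ish stripe of a
        100-aa subject: nreads, mean depth and covered fraction must agree
        with a brute-force overlay."""
        rows = []
        depth = np.zeros(100)
        for i in range(10):
            start = (i * 10) % 76 + 1
            rows.append((f"q{i}", "A", 100.0, 50.0, start, start + 24))
            depth[start - 1 : start + 24] += 1
        result = run_famli(make_set(rows, L))
        report = summarize(result)
        assert len(report) == 1
        row = report.iloc[0]
        assert row["nreads"] == 10
        assert row["depth_mean"] == pytest.approx(depth.mean())
        assert row["depth_sd"] == pytest.approx(depth.std())
        assert row["coverage_fraction"] == pytest.approx(
            np.count_nonzero(depth) / 100
        )

    def test_three_rows_for_three_true_references(self, mm_exp):
        report = summarize(mm_exp.result)
        assert len(report) == 3
        assert report["nreads"].sum() == len(mm_exp.result.assignments)


def test_params_validation():
    with pytest.raises(ValueError):
        FamliParams(prune_ratio=0.0)
    with pytest.raises(ValueError):
        FamliParams(max_iterations=0)
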