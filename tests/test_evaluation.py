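import itertools
import random

import pytest

from pseudorank.aggregation import AggregatedRanking, RankingList
from pseudorank.evaluation import (
    NEGATIVE,
    POSITIVE,
    BenchmarkDataset,
    EvalSummary,
    EvaluationError,
    RocResult,
    exceedance_curve,
    jackknife_evaluate,
    label_targets,
    pairwise_compare,
    read_summary_tsv,
    roc_n,
    write_summary_tsv,
)


def roc_n_oracle(pattern, n):
    """Brute-force truncated step-curve area for a fully returned ranking.

    ``pattern`` is a list of booleans in rank order (True = positive).
    Counts, for each of the first m false positives, the positives ranked
    strictly before it — an explicit double loop, independent of the
    implementation's single-pass accumulation.
    """
    P = sum(pattern)
    negatives = [i for i, is_pos in enumerate(pattern) if not is_pos]
    if not negatives:
        return 1.0  # all positives returned
    m = min(n, len(negatives))
    area = 0
    for fp_pos in negatives[:m]:
        area += sum(1 for i, is_pos in enumerate(pattern) if is_pos and i < fp_pos)
    return area / (m * P)


def ranking_from_pattern(pattern):
    order = [f"{'p' if is_pos else 'n'}{i:03d}" for i, is_pos in enumerate(pattern)]
    labels = {
        t: (POSITIVE if t.startswith("p") else NEGATIVE) for t in order
    }
    return order, labels


class TestBenchmarkDataset:
    def test_duplicate_seq_ids_rejected(self):
        with pytest.raises(EvaluationError, match="duplicate"):
            BenchmarkDataset(
                records=(("a", "f1", "S1", None), ("a", "f2", "S2", None))
            )

    def test_family_in_two_superfamilies_rejected(self):
        with pytest.raises(EvaluationError, match="multiple superfamilies"):
            BenchmarkDataset(
                records=(("a", "f1", "S1", None), ("b", "f1", "S2", None))
            )

    def test_needs_two_superfamilies(self):
        with pytest.raises(EvaluationError, match=">= 2 superfamilies"):
            BenchmarkDataset(
                records=(("a", "f1", "S1", None), ("b", "f2", "S1", None))
            )

    def test_from_tsv(self, tmp_path):
        path = tmp_path / "labels.tsv"
        path.write_text("a\tf1\tS1\nb\tf2\tS2\n")
        bench = BenchmarkDataset.from_tsv(path)
        assert len(bench) == 2
        assert bench.n_families() == 2
        assert bench.n_superfamilies() == 2

    def test_from_tsv_with_fasta(self, tmp_path):
        labels = tmp_path / "labels.tsv"
        labels.write_text("a\tf1\tS1\nb\tf2\tS2\n")
        fasta = tmp_path / "seqs.fasta"
        fasta.write_text(">a\nACD\n>b\nWKY\n")
        bench = BenchmarkDataset.from_tsv(labels, fasta=fasta)
        assert bench.records[0][3] == "ACD"


class TestLabelTargets:
    def test_definition(self):
        bench = BenchmarkDataset(
            records=(("q", "f1", "SF1", None), ("a", "f1", "SF1", None),
                     ("b", "f2", "SF2", None))
        )
        assert label_targets("q", bench) == {"a": POSITIVE, "b": NEGATIVE}

    def test_sole_member_superfamily_has_no_positives(self, toy_benchmark):
        labels = label_targets("e", toy_benchmark)
        assert POSITIVE not in labels.values()
        assert len(labels) == 5

    def test_counts_on_3_superfamilies(self, toy_benchmark):
        # exhaustive count oracle: sizes 3/2/1, query in the first
        labels = label_targets("q", toy_benchmark)
        assert sum(1 for v in labels.values() if v == POSITIVE) == 2
        assert sum(1 for v in labels.values() if v == NEGATIVE) == 3

    def test_exclude_same_family(self, toy_benchmark):
        labels = label_targets("q", toy_benchmark, exclude_same_family=True)
        assert "a" not in labels  # same family f1 -> neither label
        assert labels["b"] == POSITIVE  # same superfamily, other family

    def test_unknown_query(self, toy_benchmark):
        with pytest.raises(EvaluationError, match="unknown query"):
            label_targets("zzz", toy_benchmark)


class TestRocN:
    def test_perfect_ranking(self):
        order, labels = ranking_from_pattern([True, True, False, False])
        for n in (1, 2, 50):
            assert roc_n(order, labels, n) == 1.0

    def test_worst_case(self):
        order, labels = ranking_from_pattern([False, False, True, True])
        assert roc_n(order, labels, 1) == 0.0
        assert roc_n(order, labels, 2) == 0.0

    def test_interleaved_example(self):
        # [+,-,+,-]: TP(1)=1, TP(2)=2 -> (1+2)/(2*2) = 0.75
        order, labels = ranking_from_pattern([True, False, True, False])
        assert roc_n(order, labels, 2) == 0.75

    def test_zero_positives_error(self):
        order, labels = ranking_from_pattern([False, False])
        with pytest.raises(EvaluationError, match="no positives"):
            roc_n(order, labels, 1)

    def test_zero_negatives_fraction_returned(self):
        labels = {"p1": POSITIVE, "p2": POSITIVE}
        assert roc_n(["p1", "p2"], labels, 1) == 1.0
        assert roc_n(["p1"], labels, 1) == 0.5

    def test_unreturned_positive_ranks_after_all_false_positives(self):
        labels = {"p1": POSITIVE, "p2": POSITIVE, "n1": NEGATIVE}
        # only p1 and n1 returned; p2 contributes 0 to TP(1)
        assert roc_n(["p1", "n1"], labels, 1) == pytest.approx(0.5)

    def test_unreturned_negatives_rank_after_returned_entries(self):
        labels = {"p1": POSITIVE, "n1": NEGATIVE, "n2": NEGATIVE}
        # n2 unreturned: for n=2, TP(1)=1 (n1 after p1), TP(2)=1 -> 2/2=1.0
        assert roc_n(["p1", "n1"], labels, 2) == 1.0

    def test_accepts_ranking_objects(self):
        labels = {"a": POSITIVE, "b": NEGATIVE}
        agg = AggregatedRanking("q", (("a", 1.0), ("b", 0.5)))
        rl = RankingList("q", "p", (("a", 1.0), ("b", 0.5)))
        assert roc_n(agg, labels, 1) == 1.0
        assert roc_n(rl, labels, 1) == 1.0

    @pytest.mark.parametrize("n", [1, 5, 50])
    def test_exhaustive_oracle_equivalence(self, n):
        # every label pattern of every length <= 8 with >= 1 positive
        for length in range(1, 9):
            for bits in itertools.product([True, False], repeat=length):
                if not any(bits):
                    continue
                order, labels = ranking_from_pattern(list(bits))
                assert roc_n(order, labels, n) == roc_n_oracle(list(bits), n)

    def test_monotone_under_adjacent_swap(self):
        rng = random.Random(7)
        for _ in range(200):
            length = rng.randint(2, 12)
            bits = [rng.random() < 0.4 for _ in range(length)]
            if not any(bits):
                bits[0] = True
            i = rng.randrange(length - 1)
            if bits[i] or not bits[i + 1]:
                continue  # need a (-, +) adjacent pair
            swapped = bits.copy()
            swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
            for n in (1, 3, 50):
                o1, l1 = ranking_from_pattern(bits)
                o2, l2 = ranking_from_pattern(swapped)
                assert roc_n(o2, l2, n) >= roc_n(o1, l1, n)

    def test_truncation_consistency_with_full_auc(self):
        # n >= #negatives equals the full trapezoidal ROC AUC
        from sklearn.metrics import roc_auc_score

        rng = random.Random(11)
        for _ in range(50):
            length = rng.randint(4, 15)
            bits = [rng.random() < 0.5 for _ in range(length)]
            if not any(bits) or all(bits):
                continue
            order, labels = ranking_from_pattern(bits)
            scores = list(range(length, 0, -1))
            full_auc = roc_auc_score([int(b) for b in bits], scores)
            assert roc_n(order, labels, length) == pytest.approx(full_auc)


class TestJackknifeEvaluate:
    def test_label_perfect_rankings(self, toy_benchmark):
        rankings = {}
        for q in toy_benchmark.seq_ids:
            labels = label_targets(q, toy_benchmark)
            order = sorted(labels, key=lambda t: labels[t] != POSITIVE)
            rankings[q] = AggregatedRanking(
                q, tuple((t, 1.0 - i * 0.01) for i, t in enumerate(order))
            )
        summary = jackknife_evaluate(rankings, toy_benchmark)
        assert summary.mean_roc1 == 1.0
        assert summary.mean_roc50 == 1.0
        assert summary.non_evaluable == ("e",)

    def test_self_never_scored(self, toy_benchmark):
        # ranking contains the query itself at the top; it must be ignored
        entries = (("q", 1.0), ("a", 0.9), ("b", 0.8), ("c", 0.1),
                   ("d", 0.05), ("e", 0.01))
        rankings = {"q": AggregatedRanking("q", entries)}
        summary = jackknife_evaluate(rankings, toy_benchmark)
        assert summary.per_query[0].roc1 == 1.0

    def test_hand_computed_two_query_benchmark(self):
        bench = BenchmarkDataset(
            records=(("q1", "f1", "S1", None), ("q2", "f1", "S1", None),
                     ("x", "f2", "S2", None), ("y", "f3", "S3", None))
        )
        rankings = {
            # q1: [q2+, x-, y-] -> ROC1 = 1.0
            "q1": AggregatedRanking("q1", (("q2", 0.9), ("x", 0.5), ("y", 0.1))),
            # q2: [x-, q1+, y-] -> ROC1 = 0.0; ROC50: m=2, TP(1)=0, TP(2)=1 -> 0.5
            "q2": AggregatedRanking("q2", (("x", 0.9), ("q1", 0.5), ("y", 0.1))),
        }
        summary = jackknife_evaluate(rankings, bench)
        assert summary.mean_roc1 == pytest.approx(0.5)
        assert summary.mean_roc50 == pytest.approx((1.0 + 0.5) / 2)

    def test_random_rankings_near_chance(self):
        # Monte-Carlo check against the permutation expectation
        from pseudorank.simulate import SimConfig, simulate_benchmark

        cfg = SimConfig(n_superfamilies=12, families_per_superfamily=2,
                        seqs_per_family=3, seq_length=10, seed=3)
        bench = simulate_benchmark(cfg)
        rng = random.Random(5)
        n_pos = 5          # per query: superfamily size 6, minus self
        n_neg = len(bench) - 6
        m = min(50, n_neg)

        def mean_roc50_of_random(seed):
            r = random.Random(seed)
            rankings = {}
            for q in bench.seq_ids:
                others = [t for t in bench.seq_ids if t != q]
                r.shuffle(others)
                rankings[q] = AggregatedRanking(
                    q, tuple((t, 1.0 - i * 1e-3) for i, t in enumerate(others))
                )
            return jackknife_evaluate(rankings, bench).mean_roc50

        observed = sum(mean_roc50_of_random(s) for s in range(5)) / 5
        # permutation oracle: E[ROC_m] = (m + 1) / (2 (n_neg + 1))
        expected = (m + 1) / (2 * (n_neg + 1))
        assert observed == pytest.approx(expected, abs=0.05)

    def test_no_evaluable_queries_error(self, toy_benchmark):
        with pytest.raises(EvaluationError, match="no evaluable"):
            jackknife_evaluate(
                {"e": AggregatedRanking("e", (("q", 1.0),))}, toy_benchmark
            )


class TestExceedanceCurve:
    def make_summary(self, scores):
        per_query = tuple(
            RocResult(f"q{i}", s, s, 1, 1) for i, s in enumerate(scores)
        )
        k = len(scores)
        return EvalSummary(sum(scores) / k, sum(scores) / k, per_query)

    def test_all_perfect(self):
        curve = exceedance_curve(self.make_summary([1.0, 1.0]), "roc1")
        assert all(frac == 1.0 for _, frac in curve)

    def test_two_point_definition(self):
        curve = dict(exceedance_curve(self.make_summary([0.2, 0.8]), "roc1"))
        assert curve[0.0] == 1.0
        assert curve[0.2] == 1.0
        assert curve[0.8] == 0.5

    def test_matches_survival_sort_oracle(self):
        rng = random.Random(13)
        scores = [round(rng.random(), 3) for _ in range(100)]
        curve = exceedance_curve(self.make_summary(scores), "roc50")
        for t, frac in curve:
            assert frac == sum(1 for s in scores if s >= t) / len(scores)
        fractions = [f for _, f in curve]
        assert fractions == sorted(fractions, reverse=True)
        assert curve[0] == (0.0, 1.0)


class TestPairwiseCompare:
    def make_summary(self, scores):
        per_query = tuple(
            RocResult(q, s, s, 1, 1) for q, s in scores.items()
        )
        k = len(scores)
        mean = sum(scores.values()) / k
        return EvalSummary(mean, mean, per_query)

    def test_identical_all_ties(self):
        s = self.make_summary({"q1": 0.5, "q2": 0.7})
        result = pairwise_compare(s, s)
        assert (result["wins"], result["ties"], result["losses"]) == (0, 2, 0)

    def test_perfect_vs_zero(self):
        a = self.make_summary({"q1": 1.0, "q2": 1.0, "q3": 1.0})
        b = self.make_summary({"q1": 0.0, "q2": 0.0, "q3": 0.0})
        assert pairwise_compare(a, b)["wins"] == 3

    def test_counts_match_loop_oracle(self):
        rng = random.Random(17)
        sa = {f"q{i}": rng.random() for i in range(50)}
        sb = {f"q{i}": rng.random() for i in range(50)}
        result = pairwise_compare(self.make_summary(sa), self.make_summary(sb))
        wins = sum(1 for q in sa if sa[q] - sb[q] > 1e-9)
        losses = sum(1 for q in sa if sb[q] - sa[q] > 1e-9)
        assert result["wins"] == wins
        assert result["losses"] == losses
        assert result["ties"] == 50 - wins - losses

    def test_query_set_mismatch(self):
        a = self.make_summary({"q1": 1.0})
        b = self.make_summary({"q2": 1.0})
        with pytest.raises(EvaluationError, match="query sets"):
            pairwise_compare(a, b)


class TestSummaryIO:
    def test_round_trip(self, tmp_path, toy_benchmark):
        rankings = {}
        for q in toy_benchmark.seq_ids:
            others = [t for t in toy_benchmark.seq_ids if t != q]
            rankings[q] = AggregatedRanking(
                q, tuple((t, 1.0 - i * 0.1) for i, t in enumerate(others))
            )
        summary = jackknife_evaluate(rankings, toy_benchmark)
        path = tmp_path / "summary.tsv"
        write_summary_tsv(summary, path)
        back = read_summary_tsv(path)
        assert back.mean_roc1 == pytest.approx(summary.mean_roc1, abs=1e-6)
        assert back.non_evaluable == summary.non_evaluable
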