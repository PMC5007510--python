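"""Jackknife ranked-retrieval evaluation with ROC1/ROC50.

A benchmark is a set of sequences labelled with a family and a
superfamily; for each query, every other same-superfamily member is a
positive and everything else is a negative (leave-one-out).  Rankings
are scored with ROC_n: the area under the true-positive versus
false-positive step curve truncated at the n-th false positive,
normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from pseudorank.aggregation import AggregatedRanking, RankingList

POSITIVE = "positive"
NEGATIVE = "negative"

TIE_EPS = 1e-9


class EvaluationError(ValueError):
    """Raised on malformed benchmarks or impossible evaluations."""


@dataclass(frozen=True)
class BenchmarkDataset:
    """Sequences with family / superfamily labels.

    ``records`` holds ``(seq_id, family_id, superfamily_id, sequence)``
    tuples (sequence may be None).  Every family belongs to exactly one
    superfamily and at least two superfamilies must be present for the
    retrieval task to be meaningful.
    """

    records: tuple[tuple[str, str, str, str | None], ...]

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise EvaluationError("duplicate seq_ids in benchmark")
        fam_to_sf: dict[str, str] = {}
        for seq_id, fam, sf, _ in self.records:
            if fam in fam_to_sf and fam_to_sf[fam] != sf:
                raise EvaluationError(
                    f"family {fam!r} maps to multiple superfamilies"
                )
            fam_to_sf[fam] = sf
        if len(set(fam_to_sf.values())) < 2:
            raise EvaluationError("benchmark needs >= 2 superfamilies")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def seq_ids(self) -> tuple[str, ...]:
        return tuple(r[0] for r in self.records)

    @property
    def family_of(self) -> dict[str, str]:
        return {r[0]: r[1] for r in self.records}

    @property
    def superfamily_of(self) -> dict[str, str]:
        return {r[0]: r[2] for r in self.records}

    def n_families(self) -> int:
        return len({r[1] for r in self.records})

    def n_superfamilies(self) -> int:
        return len({r[2] for r in self.records})

    @classmethod
    def from_tsv(
        cls, path: str | Path, fasta: str | Path | None = None
    ) -> "BenchmarkDataset":
        """Load `seq_id <TAB> family_id <TAB> superfamily_id` lines, with
        sequences optionally attached from a FASTA file."""
        sequences: dict[str, str] = {}
        if fasta is not None:
            from Bio import SeqIO

            sequences = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta), "fasta")
            }
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise EvaluationError(
                        f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                    )
                seq_id, fam, sf = fields
                records.append((seq_id, fam, sf, sequences.get(seq_id)))
        return cls(records=tuple(records))


@dataclass(frozen=True)
class RocResult:
    query_id: str
    roc1: float
    roc50: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class EvalSummary:
    """Mean ROC1/ROC50 over evaluable queries, plus the per-query detail."""

    mean_roc1: float
    mean_roc50: float
    per_query: tuple[RocResult, ...]
    non_evaluable: tuple[str, ...] = ()

    def scores(self, metric: str) -> list[float]:
        if metric not in ("roc1", "roc50"):
            raise EvaluationError(f"unknown metric {metric!r}")
        return [getattr(r, metric) for r in self.per_query]


def label_targets(
    query_id: str,
    benchmark: BenchmarkDataset,
    exclude_same_family: bool = False,
) -> dict[str, str]:
    """Label every other benchmark member positive or negative for a query.

    Positive = shares the query's superfamily (the query itself is
    excluded: jackknife).  With ``exclude_same_family`` same-family
    members are dropped from the map entirely, counting as neither.
    """
    sf_of = benchmark.superfamily_of
    if query_id not in sf_of:
        raise EvaluationError(f"unknown query {query_id!r}")
    query_sf = sf_of[query_id]
    query_fam = benchmark.family_of[query_id]
    labels: dict[str, str] = {}
    for seq_id, fam, sf, _ in benchmark.records:
        if seq_id == query_id:
            continue
        if sf == query_sf:
            if exclude_same_family and fam == query_fam:
                continue
            labels[seq_id] = POSITIVE
        else:
            labels[seq_id] = NEGATIVE
    return labels


def roc_n(
    ranking: AggregatedRanking | RankingList | Sequence[str],
    labels: Mapping[str, str],
    n: int,
) -> float:
    """Truncated ROC area: sum_k TP(k) / (m * P).

    TP(k) is the number of positives ranked strictly before the k-th
    false positive; m = min(n, total negatives); P = total positives.
    Positives missing from the ranking rank after every returned entry
    and after all false positives (contributing nothing).  With zero
    negatives the score is the fraction of positives returned.
    """
    if n < 1:
        raise EvaluationError("n must be >= 1")
    n_pos = sum(1 for v in labels.values() if v == POSITIVE)
    n_neg = sum(1 for v in labels.values() if v == NEGATIVE)
    if n_pos == 0:
        raise EvaluationError("no positives")

    if hasattr(ranking, "target_order"):
        order: Sequence[str] = ranking.target_order
    else:
        order = ranking

    if n_neg == 0:
        returned = sum(1 for t in order if labels.get(t) == POSITIVE)
        return returned / n_pos

    m = min(n, n_neg)
    tp = 0
    fp = 0
    area = 0
    for target in order:
        label = labels.get(target)
        if label == POSITIVE:
            tp += 1
        elif label == NEGATIVE:
            fp += 1
            area += tp
            if fp == m:
                break
    # negatives never returned rank after all returned entries but before
    # any unreturned positive, so each contributes the full returned-TP count
    area += (m - fp) * tp
    return area / (m * n_pos)


def jackknife_evaluate(
    rankings: Mapping[str, AggregatedRanking | RankingList],
    benchmark: BenchmarkDataset,
    exclude_same_family: bool = False,
) -> EvalSummary:
    """Score each query's ranking with ROC1 and ROC50 and average.

    Queries whose superfamily has no other member are non-evaluable:
    they are reported but excluded from the means.
    """
    per_query: list[RocResult] = []
    non_evaluable: list[str] = []
    for query_id in sorted(rankings):
        labels = label_targets(query_id, benchmark, exclude_same_family)
        n_pos = sum(1 for v in labels.values() if v == POSITIVE)
        n_neg = len(labels) - n_pos
        if n_pos == 0:
            non_evaluable.append(query_id)
            continue
        ranking = rankings[query_id]
        per_query.append(
            RocResult(
                query_id=query_id,
                roc1=roc_n(ranking, labels, 1),
                roc50=roc_n(ranking, labels, 50),
                n_pos=n_pos,
                n_neg=n_neg,
            )
        )
    if not per_query:
        raise EvaluationError("no evaluable queries")
    k = len(per_query)
    return EvalSummary(
        mean_roc1=sum(r.roc1 for r in per_query) / k,
        mean_roc50=sum(r.roc50 for r in per_query) / k,
        per_query=tuple(per_query),
        non_evaluable=tuple(non_evaluable),
    )


def exceedance_curve(
    summary: EvalSummary, metric: str = "roc50"
) -> list[tuple[float, float]]:
    """Fraction of queries whose score is >= each threshold.

    Sampled at 0 and at every distinct per-query score; the result is a
    monotone non-increasing step function starting at fraction 1.0.
    """
    scores = summary.scores(metric)
    if not scores:
        raise EvaluationError("no evaluable queries")
    total = len(scores)
    thresholds = sorted({0.0, *scores})
    return [
        (t, sum(1 for s in scores if s >= t) / total) for t in thresholds
    ]


def pairwise_compare(
    summary_a: EvalSummary, summary_b: EvalSummary, metric: str = "roc1"
) -> dict:
    """Per-query paired scores plus win/tie/loss counts (tie within 1e-9)."""
    a_scores = {r.query_id: getattr(r, metric) for r in summary_a.per_query}
    b_scores = {r.query_id: getattr(r, metric) for r in summary_b.per_query}
    if set(a_scores) != set(b_scores):
        raise EvaluationError("query sets differ between summaries")
    pairs = []
    wins = ties = losses = 0
    for q in sorted(a_scores):
        sa, sb = a_scores[q], b_scores[q]
        pairs.append((q, sa, sb))
        if abs(sa - sb) <= TIE_EPS:
            ties += 1
        elif sa > sb:
            wins += 1
        else:
            losses += 1
    return {"pairs": pairs, "wins": wins, "ties": ties, "losses": losses}


def write_summary_tsv(summary: EvalSummary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mean_roc1: {summary.mean_roc1:.6f}\n")
        fh.write(f"# mean_roc50: {summary.mean_roc50:.6f}\n")
        fh.write("query_id\troc1\troc50\tn_pos\tn_neg\n")
        for r in summary.per_query:
            fh.write(
                f"{r.query_id}\t{r.roc1:.6f}\t{r.roc50:.6f}\t{r.n_pos}\t{r.n_neg}\n"
            )
        for q in summary.non_evaluable:
            fh.write(f"{q}\tNA\tNA\t0\tNA\n")


def read_summary_tsv(path: str | Path) -> EvalSummary:
    per_query = []
    non_evaluable = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id\t"):
                continue
            q, roc1, roc50, n_pos, n_neg = line.split("\t")
            if roc1 == "NA":
                non_evaluable.append(q)
                continue
            per_query.append(
                RocResult(q, float(roc1), float(roc50), int(n_pos), int(n_neg))
            )
    if not per_query:
        raise EvaluationError("no evaluable queries in summary file")
    k = len(per_query)
    return EvalSummary(
        mean_roc1=sum(r.roc1 for r in per_query) / k,
        mean_roc50=sum(r.roc50 for r in per_query) / k,
        per_query=tuple(per_query),
        non_evaluable=tuple(non_evaluable),
    )
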