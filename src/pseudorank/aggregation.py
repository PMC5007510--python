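"""Score fusion: min-max normalization and linear weighted rank aggregation.

Each predictor's raw scores for one query are rescaled to [0, 1] with a
per-query min-max transform; the aggregated score of a candidate target
is the weight-w_j convex combination of its normalized scores across
predictors, with absent targets contributing 0.  The fused list is
sorted by aggregated score descending.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

WEIGHT_SUM_TOL = 1e-9


class AggregationError(ValueError):
    """Raised on malformed ranking lists or aggregation models."""


@dataclass(frozen=True)
class RankingList:
    """One predictor's scored candidates for one query.

    Entries are ``(target_id, raw_score)`` with higher-is-better scores;
    they are re-sorted on construction (score descending, then target id
    ascending) so downstream order never depends on input file order.
    """

    query_id: str
    predictor_id: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        targets = [t for t, _ in self.entries]
        if len(targets) != len(set(targets)):
            raise AggregationError(
                f"duplicate target ids in ranking list for query {self.query_id!r}"
            )
        ordered = tuple(sorted(self.entries, key=lambda e: (-e[1], e[0])))
        object.__setattr__(self, "entries", ordered)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def target_order(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)


@dataclass(frozen=True)
class AggregationModel:
    """Predictor weights plus the policies for missing and degenerate scores.

    Weights must be non-negative and sum to 1.  ``missing_score_policy``
    fixes the normalized score of a target a predictor did not return
    (0 = weakest evidence); ``degenerate_norm_policy`` fixes the value
    when max == min within a list (1 = the predictor's best hits).
    """

    weights: Mapping[str, float]
    missing_score_policy: str = "zero"
    degenerate_norm_policy: str = "all_one"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights.values()):
            raise AggregationError("negative weight")
        total = sum(self.weights.values())
        if abs(total - 1.0) > WEIGHT_SUM_TOL:
            raise AggregationError(f"weights sum to {total!r}, expected 1")
        if self.missing_score_policy != "zero":
            raise AggregationError(
                f"unknown missing_score_policy {self.missing_score_policy!r}"
            )
        if self.degenerate_norm_policy != "all_one":
            raise AggregationError(
                f"unknown degenerate_norm_policy {self.degenerate_norm_policy!r}"
            )


@dataclass(frozen=True)
class AggregatedRanking:
    """Fused candidate list for one query, sorted by score descending.

    Scores lie in [0, 1]; ties are ordered by target id ascending so the
    result is fully deterministic.
    """

    query_id: str
    entries: tuple[tuple[str, float], ...]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def target_order(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.entries)


def minmax_normalize(ranking: RankingList) -> dict[str, float]:
    """Rescale one list's raw scores to [0, 1].

    norm(p) = (s(p) - min s) / (max s - min s); when every score is equal
    (including single-entry lists) every target maps to 1.0.
    """
    if not ranking.entries:
        raise AggregationError("empty ranking list")
    scores = [s for _, s in ranking.entries]
    lo, hi = min(scores), max(scores)
    if hi == lo:
        return {t: 1.0 for t, _ in ranking.entries}
    span = hi - lo
    return {t: (s - lo) / span for t, s in ranking.entries}


def aggregate(
    lists: Iterable[RankingList], model: AggregationModel
) -> AggregatedRanking:
    """Fuse several predictors' lists for one query into a single ranking.

    Over the union of targets, S(p) = sum_j w_j * norm_j(p), with
    norm_j(p) = 0 for targets predictor j did not return.  Predictors
    with a weight but no list contribute nothing.  Empty lists are
    treated as "returned nothing".
    """
    lists = list(lists)
    if not lists:
        raise AggregationError("no ranking lists to aggregate")
    query_ids = {rl.query_id for rl in lists}
    if len(query_ids) != 1:
        raise AggregationError(f"mismatched query ids: {sorted(query_ids)}")
    (query_id,) = query_ids
    seen = [rl.predictor_id for rl in lists]
    if len(seen) != len(set(seen)):
        raise AggregationError("two ranking lists share a predictor id")
    for rl in lists:
        if rl.predictor_id not in model.weights:
            raise AggregationError(f"no weight for predictor {rl.predictor_id!r}")

    scores: dict[str, float] = {}
    for rl in lists:
        if not rl.entries:
            continue
        w = model.weights[rl.predictor_id]
        for target, norm in minmax_normalize(rl).items():
            scores[target] = scores.get(target, 0.0) + w * norm
    ordered = tuple(sorted(scores.items(), key=lambda e: (-e[1], e[0])))
    return AggregatedRanking(query_id=query_id, entries=ordered)


def single_predictor_equivalence_check(ranking: RankingList) -> AggregatedRanking:
    """Aggregate a single list under weight 1.0 on its own predictor.

    Min-max normalization is strictly increasing on non-degenerate
    lists, so the output order must equal the input order; this is the
    harness for that property.
    """
    model = AggregationModel(weights={ranking.predictor_id: 1.0})
    return aggregate([ranking], model)


# --- ranking TSV I/O ---------------------------------------------------------


def read_ranking_tsv(
    path: str | Path, predictor_id: str | None = None, multi: bool = False
) -> RankingList | dict[str, RankingList]:
    """Read `query_id <TAB> target_id <TAB> score` lines into RankingLists.

    With ``multi=False`` the file must contain a single query and one
    RankingList is returned; with ``multi=True`` a dict keyed by query id
    is returned.  Duplicate (query, target) pairs keep the max score.
    """
    path = Path(path)
    pred = predictor_id or path.stem
    per_query: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise AggregationError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            q, t, s = fields
            try:
                score = float(s)
            except ValueError as exc:
                raise AggregationError(
                    f"{path}:{lineno}: bad score {s!r}"
                ) from exc
            bucket = per_query.setdefault(q, {})
            bucket[t] = max(bucket.get(t, score), score)
    result = {
        q: RankingList(
            query_id=q, predictor_id=pred, entries=tuple(targets.items())
        )
        for q, targets in per_query.items()
    }
    if multi:
        return result
    if len(result) != 1:
        raise AggregationError(
            f"{path}: expected a single query id, found {len(result)} "
            "(use multi=True / --multi for per-query splitting)"
        )
    return next(iter(result.values()))


def write_ranking_tsv(
    rankings: Iterable[RankingList | AggregatedRanking],
    path: str | Path,
    weights: Mapping[str, float] | None = None,
) -> None:
    """Write rankings back out as 3-column TSV; aggregated output records
    the weights on a leading ``# weights:`` comment line."""
    with open(path, "w") as fh:
        if weights is not None:
            tag = ",".join(f"{p}={w:g}" for p, w in sorted(weights.items()))
            fh.write(f"# weights: {tag}\n")
        for ranking in rankings:
            for target, score in ranking.entries:
                fh.write(f"{ranking.query_id}\t{target}\t{score:.10g}\n")
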