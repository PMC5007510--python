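"""Exhaustive simplex grid search for aggregation weights.

The printed weights of the combined predictor are multiples of 0.01, so
the search space is reconstructed as the standard simplex discretized at
a fixed step; every grid point is evaluated by aggregating the
predictors' lists and running the jackknife evaluation, and the argmax
of the chosen objective wins (ties: lexicographically first point).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

from pseudorank.aggregation import (
    AggregatedRanking,
    AggregationError,
    AggregationModel,
    RankingList,
    minmax_normalize,
)
from pseudorank.evaluation import BenchmarkDataset, EvalSummary, jackknife_evaluate

GRID_TOL = 1e-9


class WeightSearchError(ValueError):
    pass


@dataclass(frozen=True)
class WeightGrid:
    """All k-tuples of non-negative multiples of ``step`` summing to 1."""

    step: float
    k: int
    points: tuple[tuple[float, ...], ...]

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class SearchResult:
    best_weights: dict[str, float]
    best_score: float
    objective: str
    trace: tuple[tuple[tuple[float, ...], float], ...]


def enumerate_simplex(k: int, step: float) -> WeightGrid:
    """Enumerate the simplex grid in lexicographic order.

    1/step must be an integer; the grid has C(1/step + k - 1, k - 1)
    points.  Coordinates are emitted as exact multiples i/n to avoid
    accumulation error.
    """
    if k < 1:
        raise WeightSearchError("k must be >= 1")
    if step <= 0 or step > 1:
        raise WeightSearchError("step must lie in (0, 1]")
    n = round(1.0 / step)
    if abs(1.0 / step - n) > GRID_TOL:
        raise WeightSearchError(f"1/step = {1.0 / step!r} is not an integer")

    points: list[tuple[float, ...]] = []

    def compose(remaining: int, parts: int, prefix: tuple[int, ...]) -> None:
        if parts == 1:
            points.append(prefix + (remaining,))
            return
        for i in range(remaining + 1):
            compose(remaining - i, parts - 1, prefix + (i,))

    compose(n, k, ())
    grid = tuple(tuple(i / n for i in p) for p in points)
    assert len(grid) == comb(n + k - 1, k - 1)
    return WeightGrid(step=step, k=k, points=grid)


def grid_search_weights(
    lists: Mapping[str, Mapping[str, RankingList]],
    benchmark: BenchmarkDataset,
    grid: WeightGrid,
    objective: str = "mean_roc1",
    exclude_same_family: bool = False,
) -> SearchResult:
    """Evaluate every grid point and return the argmax of the objective.

    ``lists`` maps predictor_id -> query_id -> RankingList.  Per-query
    min-max normalization does not depend on the weights, so it is
    computed once up front; each grid point then only re-weights the
    cached normalized scores.
    """
    if objective not in ("mean_roc1", "mean_roc50"):
        raise WeightSearchError(f"unknown objective {objective!r}")
    if not grid.points:
        raise WeightSearchError("empty grid")
    predictors = sorted(lists)
    if grid.k != len(predictors):
        raise WeightSearchError(
            f"grid is {grid.k}-dimensional but {len(predictors)} predictors given"
        )

    queries = sorted({q for per_query in lists.values() for q in per_query})
    # predictor -> query -> {target: normalized score}
    norms: dict[str, dict[str, dict[str, float]]] = {}
    for pred in predictors:
        norms[pred] = {}
        for q in queries:
            rl = lists[pred].get(q)
            norms[pred][q] = (
                minmax_normalize(rl) if rl is not None and len(rl) else {}
            )

    trace: list[tuple[tuple[float, ...], float]] = []
    best_point: tuple[float, ...] | None = None
    best_score = float("-inf")
    for point in grid.points:
        rankings = {
            q: _weighted_ranking(q, predictors, point, norms) for q in queries
        }
        summary = jackknife_evaluate(rankings, benchmark, exclude_same_family)
        score = summary.mean_roc1 if objective == "mean_roc1" else summary.mean_roc50
        trace.append((point, score))
        if score > best_score:  # strict: ties keep the earlier (lexicographic) point
            best_score = score
            best_point = point

    assert best_point is not None
    return SearchResult(
        best_weights=dict(zip(predictors, best_point)),
        best_score=best_score,
        objective=objective,
        trace=tuple(trace),
    )


def _weighted_ranking(
    query_id: str,
    predictors: Sequence[str],
    point: Sequence[float],
    norms: Mapping[str, Mapping[str, Mapping[str, float]]],
) -> AggregatedRanking:
    scores: dict[str, float] = {}
    for pred, w in zip(predictors, point):
        # zero-weight predictors still contribute their targets to the union
        for target, norm in norms[pred][query_id].items():
            scores[target] = scores.get(target, 0.0) + w * norm
    ordered = tuple(sorted(scores.items(), key=lambda e: (-e[1], e[0])))
    return AggregatedRanking(query_id=query_id, entries=ordered)
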