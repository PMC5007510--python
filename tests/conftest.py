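import pytest

from pseudorank.aggregation import RankingList
from pseudorank.evaluation import BenchmarkDataset


@pytest.fixture
def toy_benchmark() -> BenchmarkDataset:
    """3 superfamilies of sizes 3 / 2 / 1."""
    return BenchmarkDataset(
        records=(
            ("q", "f1", "SF1", None),
            ("a", "f1", "SF1", None),
            ("b", "f2", "SF1", None),
            ("c", "f3", "SF2", None),
            ("d", "f3", "SF2", None),
            ("e", "f4", "SF3", None),
        )
    )


def make_ranking(query="q", predictor="p", scores=None) -> RankingList:
    scores = scores or {}
    return RankingList(
        query_id=query, predictor_id=predictor, entries=tuple(scores.items())
    )
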