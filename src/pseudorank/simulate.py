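"""Seeded synthetic benchmarks, MSAs and predictor score lists.

The generator mirrors the structure of the retrieval task: superfamily
ancestor sequences are drawn uniformly at random, family ancestors are
per-site substitutions of their superfamily ancestor, members are
substitutions of the family ancestor.  Predictor scores are an indicator
homology signal plus independent Gaussian noise, so different predictors
err on different queries — the complementarity the aggregation exploits.

All operations are fully deterministic under a fixed seed (PCG64).
Nothing here aims at biological realism; see the package docs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from pseudorank.aggregation import RankingList
from pseudorank.evaluation import BenchmarkDataset
from pseudorank.profiles import CANONICAL_ALPHABET, Msa


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the synthetic benchmark.

    Mutation rates are per-site substitution probabilities, where a
    substitution redraws the residue uniformly from all 20 (so rate 1
    gives an unrelated uniform sequence, with the chance 1/20 identity).
    ``predictor_signals`` maps predictor ids to the mean score bonus a
    true same-superfamily pair receives.
    """

    n_superfamilies: int = 10
    families_per_superfamily: int = 2
    seqs_per_family: int = 4
    seq_length: int = 60
    within_family_mut_rate: float = 0.05
    within_superfamily_mut_rate: float = 0.3
    background: float = 0.0
    predictor_signals: Mapping[str, float] = field(
        default_factory=lambda: {"p1": 3.0, "p2": 1.5, "p3": 0.0}
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_superfamilies", "families_per_superfamily", "seqs_per_family", "seq_length"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        for name in ("within_family_mut_rate", "within_superfamily_mut_rate", "background"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if self.within_family_mut_rate > self.within_superfamily_mut_rate:
            raise SimulationError(
                "within_family_mut_rate must not exceed within_superfamily_mut_rate"
            )
        if self.noise_sd <= 0:
            raise SimulationError("noise_sd must be > 0")
        if any(a < 0 for a in self.predictor_signals.values()):
            raise SimulationError("predictor signals must be >= 0")


_ALPHABET = np.frombuffer(CANONICAL_ALPHABET.encode(), dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 20, size=length)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Redraw each site uniformly over all 20 residues with prob ``rate``."""
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    out[hit] = rng.integers(0, 20, size=int(hit.sum()))
    return out


def _decode(seq: np.ndarray) -> str:
    return _ALPHABET[seq].tobytes().decode()


def simulate_benchmark(cfg: SimConfig) -> BenchmarkDataset:
    """Generate a labelled family/superfamily benchmark with sequences."""
    rng = np.random.default_rng(cfg.seed)
    records = []
    for s in range(cfg.n_superfamilies):
        sf_id = f"sf{s:03d}"
        sf_ancestor = _random_sequence(rng, cfg.seq_length)
        for f in range(cfg.families_per_superfamily):
            fam_id = f"{sf_id}.fam{f:02d}"
            fam_ancestor = _mutate(sf_ancestor, cfg.within_superfamily_mut_rate, rng)
            for m in range(cfg.seqs_per_family):
                seq_id = f"{fam_id}.s{m:02d}"
                member = _mutate(fam_ancestor, cfg.within_family_mut_rate, rng)
                records.append((seq_id, fam_id, sf_id, _decode(member)))
    return BenchmarkDataset(records=tuple(records))


def simulate_msa(
    member_sequence: str,
    n_rows: int,
    conservation: Sequence[float],
    seed: int,
) -> Msa:
    """Build an MSA around a member sequence with per-column conservation.

    Row 0 is the unmutated master; each further row keeps the member
    residue at column c with probability ``conservation[c]`` and
    otherwise substitutes a uniformly chosen *other* residue.
    """
    if len(conservation) != len(member_sequence):
        raise SimulationError(
            f"conservation length {len(conservation)} != sequence length "
            f"{len(member_sequence)}"
        )
    if n_rows < 1:
        raise SimulationError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    cons = np.asarray(conservation, dtype=float)
    master = np.frombuffer(member_sequence.encode(), dtype=np.uint8)
    idx_of = {c: i for i, c in enumerate(CANONICAL_ALPHABET)}
    master_idx = np.array([idx_of[chr(c)] for c in master])

    rows = [("row000", member_sequence)]
    for r in range(1, n_rows):
        keep = rng.random(len(master_idx)) < cons
        # uniform over the 19 *other* residues via a shifted draw
        shift = rng.integers(1, 20, size=len(master_idx))
        mutated = (master_idx + shift) % 20
        row = np.where(keep, master_idx, mutated)
        rows.append((f"row{r:03d}", _decode(row)))
    return Msa(query_id="row000", rows=tuple(rows), master_index=0)


def simulate_scores(
    benchmark: BenchmarkDataset,
    predictor_signals: Mapping[str, float],
    noise_sd: float,
    seed: int,
) -> dict[str, dict[str, RankingList]]:
    """Draw per-predictor score lists: signal * 1[same superfamily] + noise.

    Returns predictor_id -> query_id -> RankingList over all other
    benchmark members, with noise independent across predictors and
    pairs.  Deterministic given the seed.
    """
    if noise_sd <= 0:
        raise SimulationError("noise_sd must be > 0")
    rng = np.random.default_rng(seed)
    seq_ids = list(benchmark.seq_ids)
    sf_of = benchmark.superfamily_of
    n = len(seq_ids)
    same_sf = np.array(
        [[sf_of[a] == sf_of[b] for b in seq_ids] for a in seq_ids], dtype=float
    )
    out: dict[str, dict[str, RankingList]] = {}
    for pred in sorted(predictor_signals):
        a_j = predictor_signals[pred]
        noise = rng.normal(0.0, noise_sd, size=(n, n))
        raw = a_j * same_sf + noise
        per_query: dict[str, RankingList] = {}
        for i, q in enumerate(seq_ids):
            entries = tuple(
                (seq_ids[j], float(raw[i, j])) for j in range(n) if j != i
            )
            per_query[q] = RankingList(query_id=q, predictor_id=pred, entries=entries)
        out[pred] = per_query
    return out


def write_benchmark_tsv(benchmark: BenchmarkDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, fam, sf, _ in benchmark.records:
            fh.write(f"{seq_id}\t{fam}\t{sf}\n")


def write_benchmark_fasta(benchmark: BenchmarkDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for seq_id, _, _, seq in benchmark.records:
            if seq is None:
                continue
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
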