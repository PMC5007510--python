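"""Parsers for native predictor output formats, plus optional invocation.

Each parser turns one tool's per-query hit report into a
:class:`~pseudorank.aggregation.RankingList` with a uniform
higher-is-better score (bit scores preferred; -log10 E-value where only
E-values exist).  Multiple hits to the same target collapse to the max
score, since the rank vector carries one score per candidate.

``run_predictor`` can shell out to a user-installed binary with the
documented parameters; the test suite never invokes live binaries.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path

from pseudorank.aggregation import RankingList, read_ranking_tsv

#: floor applied before -log10 so E = 0 maps to a finite ceiling of 300
EVALUE_FLOOR = 1e-300

#: documented invocation parameters (search-time); profile generation for
#: the pseudo-sequence path uses psiblast -j 10 -e 0.001 separately
INVOCATION_PARAMS = {
    "psiblast": "psiblast -num_iterations 3 -outfmt 6",
    "hhblits": "hhblits -n 2",
    "hmmer": "phmmer --tblout <out> (default parameters)",
    "coma": "coma (default parameters; convert output to generic TSV)",
}


class AdapterError(ValueError):
    pass


@dataclass(frozen=True)
class AdapterSpec:
    """Which tool produced a ranking and how to score its hits."""

    predictor_id: str  # {psiblast, hhblits, hmmer, coma, generic}
    score_field: str = "bit_score"  # {bit_score, neg_log_evalue, raw_column}
    invocation_params: str = ""

    def __post_init__(self) -> None:
        if self.predictor_id not in ("psiblast", "hhblits", "hmmer", "coma", "generic"):
            raise AdapterError(f"unknown predictor {self.predictor_id!r}")
        if self.score_field not in ("bit_score", "neg_log_evalue", "raw_column"):
            raise AdapterError(f"unknown score field {self.score_field!r}")


def neg_log_evalue(evalue: float) -> float:
    """Higher-is-better transform of an E-value, clamped at E = 1e-300."""
    import math

    return -math.log10(max(evalue, EVALUE_FLOOR))


def parse_blast_tabular(
    path: str | Path, predictor_id: str = "psiblast"
) -> RankingList:
    """Parse BLAST ``-outfmt 6`` (12 standard columns); score = bit score."""
    path = Path(path)
    query_id = None
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise AdapterError(
                    f"{path}:{lineno}: expected 12 columns, got {len(fields)}"
                )
            q, target = fields[0], fields[1]
            try:
                bits = float(fields[11])
            except ValueError as exc:
                raise AdapterError(
                    f"{path}:{lineno}: bad bit score {fields[11]!r}"
                ) from exc
            if query_id is None:
                query_id = q
            elif q != query_id:
                raise AdapterError(
                    f"{path}:{lineno}: multiple query ids in one file"
                )
            scores[target] = max(scores.get(target, bits), bits)
    if query_id is None:
        raise AdapterError(f"{path}: no hits found")
    return RankingList(
        query_id=query_id, predictor_id=predictor_id, entries=tuple(scores.items())
    )


def parse_hmmer_tblout(path: str | Path, predictor_id: str = "hmmer") -> RankingList:
    """Parse HMMER3 ``--tblout``; score = full-sequence bit score (field 6)."""
    path = Path(path)
    query_id = None
    scores: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 18:
                raise AdapterError(
                    f"{path}:{lineno}: expected >= 18 whitespace-separated "
                    f"fields, got {len(fields)}"
                )
            target, q = fields[0], fields[2]
            try:
                bits = float(fields[5])
            except ValueError as exc:
                raise AdapterError(
                    f"{path}:{lineno}: bad score {fields[5]!r}"
                ) from exc
            if query_id is None:
                query_id = q
            elif q != query_id:
                raise AdapterError(
                    f"{path}:{lineno}: multiple query ids in one file"
                )
            scores[target] = max(scores.get(target, bits), bits)
    if query_id is None:
        raise AdapterError(f"{path}: no hits found")
    return RankingList(
        query_id=query_id, predictor_id=predictor_id, entries=tuple(scores.items())
    )


def parse_hhr(path: str | Path, predictor_id: str = "hhblits") -> RankingList:
    """Parse the summary hit table of an HHblits/HHsearch ``.hhr`` report.

    Score = the table's Score column (already higher-is-better).  An
    empty hit table yields an empty RankingList.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    query_id = None
    table_start = None
    for idx, line in enumerate(lines):
        if line.startswith("Query"):
            parts = line.split()
            if len(parts) >= 2:
                query_id = parts[1]
        if line.lstrip().startswith("No Hit"):
            table_start = idx + 1
            break
    if table_start is None:
        raise AdapterError(f"{path}: missing summary table ('No Hit' header)")
    if query_id is None:
        raise AdapterError(f"{path}: missing Query line")

    scores: dict[str, float] = {}
    for lineno, line in enumerate(lines[table_start:], start=table_start + 1):
        if not line.strip():
            break  # blank line ends the summary table
        # fixed layout: rank in cols 0-3, hit id+description in cols 4-34,
        # then Prob  E-value  P-value  Score  SS  Cols  ranges
        rank_field = line[:4].strip()
        if not rank_field.isdigit():
            break
        target = line[4:35].split()
        numeric = line[35:].split()
        if not target or len(numeric) < 4:
            raise AdapterError(f"{path}:{lineno}: malformed hit line")
        try:
            score = float(numeric[3])
        except ValueError as exc:
            raise AdapterError(
                f"{path}:{lineno}: bad Score field {numeric[3]!r}"
            ) from exc
        tid = target[0]
        scores[tid] = max(scores.get(tid, score), score)
    return RankingList(
        query_id=query_id, predictor_id=predictor_id, entries=tuple(scores.items())
    )


def parse_generic_tsv(
    path: str | Path,
    predictor_id: str | None = None,
    multi: bool = False,
) -> RankingList | dict[str, RankingList]:
    """Parse 3-column `query_id target_id score` TSV (the Coma path:
    users pre-convert Coma output to this format)."""
    return read_ranking_tsv(path, predictor_id=predictor_id, multi=multi)


def run_predictor(
    spec: AdapterSpec, pseudo_fasta: str | Path, database_path: str | Path
) -> RankingList:
    """Invoke a user-installed predictor binary and parse its output.

    Optional plumbing: requires the named binary on PATH.  PSI-BLAST
    runs 3 search iterations, HHblits 2, Hmmer/Coma defaults.
    """
    binaries = {
        "psiblast": "psiblast",
        "hhblits": "hhblits",
        "hmmer": "phmmer",
        "coma": "coma",
    }
    if spec.predictor_id == "generic":
        raise AdapterError("generic adapter has no binary; parse a TSV instead")
    binary = binaries[spec.predictor_id]
    if shutil.which(binary) is None:
        raise AdapterError(
            f"predictor not installed: {binary!r} not found on PATH "
            f"(install it and re-run; documented invocation: "
            f"{INVOCATION_PARAMS[spec.predictor_id]})"
        )
    import tempfile

    with tempfile.TemporaryDirectory() as tmp:
        out = Path(tmp) / "hits.out"
        if spec.predictor_id == "psiblast":
            cmd = [
                binary,
                "-query", str(pseudo_fasta),
                "-db", str(database_path),
                "-num_iterations", "3",
                "-outfmt", "6",
                "-out", str(out),
            ]
        elif spec.predictor_id == "hhblits":
            cmd = [
                binary,
                "-i", str(pseudo_fasta),
                "-d", str(database_path),
                "-n", "2",
                "-o", str(out),
            ]
        elif spec.predictor_id == "hmmer":
            cmd = [
                binary,
                "--tblout", str(out),
                str(pseudo_fasta),
                str(database_path),
            ]
        else:  # coma
            cmd = [binary, str(pseudo_fasta), str(database_path)]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise AdapterError(
                f"{binary} exited with status {proc.returncode}: {proc.stderr}"
            )
        if spec.predictor_id == "psiblast":
            return parse_blast_tabular(out, predictor_id=spec.predictor_id)
        if spec.predictor_id == "hhblits":
            return parse_hhr(out, predictor_id=spec.predictor_id)
        if spec.predictor_id == "hmmer":
            return parse_hmmer_tblout(out, predictor_id=spec.predictor_id)
        raise AdapterError("coma output must be converted to generic TSV")
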