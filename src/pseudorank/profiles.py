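"""Frequency profiles and profile-based pseudo protein sequences.

A query's frequency profile is a 20 x L matrix of per-position amino-acid
frequencies (L = ungapped query length), built either from a multiple
sequence alignment or from the weighted-observed-frequency block of a
PSI-BLAST ASCII PSSM.  The pseudo protein sequence is the per-column
argmax residue of that profile: a consensus string that carries the
profile's evolutionary information while remaining a plain sequence any
downstream search tool can consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

#: The 20 canonical amino acids, alphabetical. Non-canonical codes
#: (B, Z, X, U, O, J, '*') and gaps never enter profile denominators.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_ALPHABET)

GAP_CHARS = frozenset("-.")


class ProfileError(ValueError):
    """Raised for malformed MSAs, profiles, or PSSM files."""


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment with a designated master (query) row.

    Rows are ``(seq_id, aligned_string)`` pairs; gaps are ``'-'`` (or
    ``'.'``).  The master row is the query whose ungapped positions index
    the profile columns.
    """

    query_id: str
    rows: tuple[tuple[str, str], ...]
    master_index: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ProfileError("empty alignment")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ProfileError("ragged alignment: rows have unequal lengths")
        if not 0 <= self.master_index < len(self.rows):
            raise ProfileError(
                f"master row index {self.master_index} out of range "
                f"(alignment has {len(self.rows)} rows)"
            )

    @property
    def master_row(self) -> str:
        return self.rows[self.master_index][1]

    @property
    def width(self) -> int:
        return len(self.rows[0][1])


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-position amino-acid frequency distribution for one query.

    ``columns[i]`` maps each of the 20 canonical residues to its
    frequency at ungapped master position ``i``; ``query_residues[i]`` is
    the master residue there.  Counted columns sum to 1; a column of all
    zeros marks a position where no canonical residue was observed (the
    pseudo-sequence step then falls back to the master residue).
    """

    query_id: str
    columns: tuple[Mapping[str, float], ...]
    query_residues: str

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.query_residues):
            raise ProfileError(
                "profile length mismatch: "
                f"{len(self.columns)} columns vs {len(self.query_residues)} residues"
            )
        for i, col in enumerate(self.columns):
            if set(col) != _CANONICAL_SET:
                raise ProfileError(f"column {i} does not cover the canonical alphabet")
            total = sum(col.values())
            if total and abs(total - 1.0) > 1e-9:
                raise ProfileError(f"column {i} frequencies sum to {total!r}, not 1")
            if any(f < 0 or f > 1 for f in col.values()):
                raise ProfileError(f"column {i} has a frequency outside [0, 1]")

    def __len__(self) -> int:
        return len(self.columns)


@dataclass(frozen=True)
class PseudoSequence:
    """The per-column argmax consensus of a frequency profile."""

    query_id: str
    residues: str
    source: str = "msa"  # {"msa", "pssm"}

    def __len__(self) -> int:
        return len(self.residues)


def msa_to_frequency_profile(msa: Msa) -> FrequencyProfile:
    """Count per-column residue frequencies over the MSA.

    One profile column is emitted per non-gap master position, in master
    order.  The denominator of each column counts only canonical,
    non-gap residues; gap-only or all-non-canonical columns yield an
    all-zero column.
    """
    master = msa.master_row
    kept = [i for i, c in enumerate(master) if c not in GAP_CHARS]
    if not kept:
        raise ProfileError("master row contains no non-gap characters")

    columns: list[dict[str, float]] = []
    residues: list[str] = []
    for i in kept:
        counts = dict.fromkeys(CANONICAL_ALPHABET, 0)
        for _, seq in msa.rows:
            c = seq[i].upper()
            if c in _CANONICAL_SET:
                counts[c] += 1
        total = sum(counts.values())
        if total:
            columns.append({aa: n / total for aa, n in counts.items()})
        else:
            columns.append(dict.fromkeys(CANONICAL_ALPHABET, 0.0))
        residues.append(master[i].upper())
    return FrequencyProfile(
        query_id=msa.query_id, columns=tuple(columns), query_residues="".join(residues)
    )


def profile_to_pseudo_sequence(
    profile: FrequencyProfile, source: str = "msa"
) -> PseudoSequence:
    """Take the maximal-frequency residue at every profile column.

    Ties are broken in favour of the master residue when it is among the
    tied maxima, else the alphabetically first tied residue wins.  An
    all-zero column falls back to the master residue so the output never
    contains a non-residue.
    """
    out: list[str] = []
    for col, master_res in zip(profile.columns, profile.query_residues):
        best = max(col.values())
        if best == 0.0:
            out.append(master_res)
            continue
        tied = [aa for aa in CANONICAL_ALPHABET if col[aa] == best]
        out.append(master_res if master_res in tied else tied[0])
    return PseudoSequence(
        query_id=profile.query_id, residues="".join(out), source=source
    )


# --- PSI-BLAST ASCII PSSM (-out_ascii_pssm) ---------------------------------

_NUM_RE = re.compile(r"-?\d+(?:\.\d+)?")


def parse_ascii_pssm(path: str | Path, query_id: str | None = None) -> FrequencyProfile:
    """Read the weighted-observed-frequency (percentage) block of a PSSM.

    The ASCII PSSM written by ``psiblast -out_ascii_pssm`` carries, per
    query position, 20 log-odds columns followed by 20 percentage
    columns.  Frequencies are the percentages divided by 100; the master
    residue comes from the second field of each row.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    freq_order: list[str] = []
    for idx, line in enumerate(lines):
        letters = line.split()
        if len(letters) >= 40 and all(
            len(t) == 1 and t in _CANONICAL_SET for t in letters[:40]
        ):
            header_idx = idx
            freq_order = letters[20:40]
            break
    if header_idx is None:
        raise ProfileError(f"no frequency block in {path}")

    columns: list[dict[str, float]] = []
    residues: list[str] = []
    for offset, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            break  # blank line terminates the matrix
        fields = line.split()
        if not fields[0].isdigit():
            break  # trailing K/Lambda statistics
        if len(fields) < 42 or len(fields[1]) != 1:
            raise ProfileError(f"{path}:{offset}: malformed PSSM row")
        try:
            values = [float(v) for v in fields[2:42]]
        except ValueError as exc:
            raise ProfileError(f"{path}:{offset}: malformed PSSM row ({exc})") from exc
        percentages = values[20:40]
        col = dict.fromkeys(CANONICAL_ALPHABET, 0.0)
        for aa, pct in zip(freq_order, percentages):
            col[aa] = pct / 100.0
        total = sum(col.values())
        if total and abs(total - 1.0) <= 0.02:
            # percentage blocks are integer-rounded; renormalize exactly
            col = {aa: v / total for aa, v in col.items()}
        elif total:
            raise ProfileError(
                f"{path}:{offset}: percentage block sums to {100 * total:.1f}%"
            )
        columns.append(col)
        residues.append(fields[1].upper())
    if not columns:
        raise ProfileError(f"no frequency block in {path}")
    return FrequencyProfile(
        query_id=query_id or path.stem,
        columns=tuple(columns),
        query_residues="".join(residues),
    )


# --- FASTA I/O ---------------------------------------------------------------


def read_msa_fasta(path: str | Path, master_id: str | None = None) -> Msa:
    """Load an aligned FASTA file; the master row is the first record
    unless ``master_id`` names another one."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ProfileError("empty alignment")
    rows = tuple((r.id, str(r.seq)) for r in records)
    if master_id is None:
        master_index = 0
    else:
        ids = [r.id for r in records]
        if master_id not in ids:
            raise ProfileError(f"master id {master_id!r} not found in alignment")
        master_index = ids.index(master_id)
    return Msa(query_id=rows[master_index][0], rows=rows, master_index=master_index)


def write_pseudo_fasta(pseudos: Iterable[PseudoSequence], path: str | Path) -> None:
    """Write pseudo sequences as FASTA, tagging each header with ``pseudo=1``."""
    with open(path, "w") as fh:
        for ps in pseudos:
            fh.write(f">{ps.query_id} pseudo=1\n")
            for i in range(0, len(ps.residues), 60):
                fh.write(ps.residues[i : i + 60] + "\n")
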