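"""Multiple sequence alignment container, I/O and preprocessing filters.

Alignments are equal-length rows over the 20 standard amino acids plus the
gap symbol ``-``.  Preprocessing mirrors the standard curation applied to
Pfam-style alignments before covariation analysis: removal of sequences
with uncommon insertions/deletions relative to a reference (seed) alignment
(90% column-occupancy rule) and greedy redundancy removal at 80% pairwise
identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
ALPHABET = AMINO_ACIDS + GAP

_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP_CODE = _AA_INDEX[GAP]


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignment inputs."""


@dataclass(frozen=True)
class Alignment:
    """An immutable gapped protein multiple sequence alignment.

    Parameters
    ----------
    ids
        Unique sequence identifiers, one per row.
    rows
        Equal-length strings over the 21-symbol alphabet (20 amino acids
        plus ``-``).  Lowercase letters and ``.`` gaps are normalized on
        construction.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    _codes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = tuple(self.ids)
        rows = tuple(r.upper().replace(".", GAP) for r in self.rows)
        if len(ids) != len(rows):
            raise AlignmentError("ids and rows must have equal length")
        if len(rows) < 1:
            raise AlignmentError("alignment requires at least 1 sequence")
        if len(set(ids)) != len(ids):
            raise AlignmentError("sequence identifiers must be unique")
        ncol = len(rows[0])
        if ncol < 2:
            raise AlignmentError("alignment requires at least 2 columns")
        for sid, row in zip(ids, rows):
            if len(row) != ncol:
                raise AlignmentError(
                    f"unequal row lengths: sequence {sid!r} has length "
                    f"{len(row)}, expected {ncol}"
                )
            for col, ch in enumerate(row):
                if ch not in _AA_INDEX:
                    raise AlignmentError(
                        f"character {ch!r} outside amino-acid alphabet in "
                        f"sequence {sid!r}, column {col + 1}"
                    )
        codes = np.frombuffer(
            "".join(rows).encode("ascii"), dtype=np.uint8
        ).reshape(len(rows), ncol)
        lut = np.full(128, 255, dtype=np.uint8)
        for ch, i in _AA_INDEX.items():
            lut[ord(ch)] = i
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "_codes", lut[codes])

    @property
    def n_seq(self) -> int:
        return len(self.rows)

    @property
    def n_col(self) -> int:
        return len(self.rows[0])

    @property
    def codes(self) -> np.ndarray:
        """(n_seq, n_col) uint8 matrix; amino acids 0..19, gap 20."""
        return self._codes

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    def subset(self, keep: Iterable[int]) -> "Alignment":
        keep = list(keep)
        return Alignment(
            ids=tuple(self.ids[k] for k in keep),
            rows=tuple(self.rows[k] for k in keep),
        )


@dataclass(frozen=True)
class ColumnMask:
    """Ordered set of 0-based column indices eligible for covariation."""

    ungapped: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = tuple(int(i) for i in self.ungapped)
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise AlignmentError("column indices must be strictly increasing")
        if any(i < 0 for i in idx):
            raise AlignmentError("column indices must be non-negative")
        object.__setattr__(self, "ungapped", idx)

    def __len__(self) -> int:
        return len(self.ungapped)

    def __iter__(self):
        return iter(self.ungapped)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment from a FASTA or Stockholm file.

    Gap characters ``.`` and ``-`` are both normalized to ``-`` and letters
    are uppercased.  Raises :class:`AlignmentError` for rows of unequal
    length, characters outside the alphabet, or an empty file.
    """
    fmt = format.lower()
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format: {format!r}")
    path = Path(path)
    if fmt == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise AlignmentError(f"cannot parse {path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    return Alignment(
        ids=tuple(r.id for r in records),
        rows=tuple(str(r.seq) for r in records),
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as FASTA."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def filter_gapped_sequences(
    aln: Alignment, reference: Alignment, occupancy: float = 0.9
) -> Alignment:
    """Remove sequences with gaps/insertions atypical of the reference.

    A sequence is removed if it has a gap at any column where at least
    ``occupancy`` of the reference sequences are non-gap, or a residue at
    any column where at least ``occupancy`` of the reference sequences are
    gapped.  Survivors are returned in input order.
    """
    if aln.n_col != reference.n_col:
        raise AlignmentError(
            f"column-count mismatch: {aln.n_col} vs reference {reference.n_col}"
        )
    ref_gap_frac = (reference.codes == GAP_CODE).mean(axis=0)
    mostly_occupied = (1.0 - ref_gap_frac) >= occupancy
    mostly_gapped = ref_gap_frac >= occupancy
    is_gap = aln.codes == GAP_CODE
    bad = (is_gap & mostly_occupied).any(axis=1) | (
        ~is_gap & mostly_gapped
    ).any(axis=1)
    return aln.subset(np.flatnonzero(~bad))


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical columns, excluding columns gapped in both.

    Columns where exactly one sequence is gapped count as mismatches.
    Returns 0.0 when every column is gapped in both sequences.
    """
    a = np.frombuffer(row_a.encode(), dtype=np.uint8)
    b = np.frombuffer(row_b.encode(), dtype=np.uint8)
    gap = ord(GAP)
    both_gap = (a == gap) & (b == gap)
    denom = int((~both_gap).sum())
    if denom == 0:
        return 0.0
    matches = int(((a == b) & ~both_gap).sum())
    return matches / denom


def redundancy_filter(aln: Alignment, identity_threshold: float = 0.8) -> Alignment:
    """Greedy first-seen redundancy removal.

    Iterates sequences in input order; a sequence is kept iff its pairwise
    identity to every previously kept sequence is strictly below
    ``identity_threshold`` (sequences at or above the threshold — "80%
    redundancy or greater" — are removed).
    """
    if not 0.0 < identity_threshold <= 1.0:
        raise ValueError(
            f"identity_threshold must be in (0, 1], got {identity_threshold}"
        )
    kept: list[int] = []
    for i, row in enumerate(aln.rows):
        if all(
            pairwise_identity(row, aln.rows[j]) < identity_threshold
            for j in kept
        ):
            kept.append(i)
    return aln.subset(kept)


def ungapped_columns(aln: Alignment) -> ColumnMask:
    """Columns containing zero gap characters."""
    gap_free = ~(aln.codes == GAP_CODE).any(axis=0)
    return ColumnMask(tuple(int(i) for i in np.flatnonzero(gap_free)))


def removal_report(
    original: Alignment,
    after_gap_filter: Alignment,
    after_redundancy: Alignment,
) -> list[tuple[str, str]]:
    """(sequence id, reason) for every sequence removed by the filters."""
    survivors_gap = set(after_gap_filter.ids)
    survivors_final = set(after_redundancy.ids)
    report = []
    for sid in original.ids:
        if sid not in survivors_gap:
            report.append((sid, "atypical_gap_pattern"))
        elif sid not in survivors_final:
            report.append((sid, "redundant"))
    return report
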