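"""Alignment containers, FASTA I/O, gap handling and translation.

All downstream statistics in this package operate on three containers
defined here:

* :class:`SequenceRecord` — a single labelled sequence,
* :class:`Alignment` — an ordered, equal-length collection of records
  (nucleotide or protein),
* :class:`CodonAlignment` — an in-frame nucleotide alignment suitable for
  codon-aware statistics (synonymous/non-synonymous partitioning).

Gap handling follows the "complete deletion" convention used throughout
the diversity and neutrality modules: any column containing a gap in any
sequence is removed before statistics are computed
(:func:`strip_gap_columns`).  A pairwise-deletion mode is provided where a
statistic explicitly needs it (protein distances; see ``sfbkit.trees``).

Sequences are assumed to be curated, pre-aligned coding regions; no
alignment or ORF detection is performed here.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterator, Literal, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "AlignmentError",
    "InputError",
    "SequenceRecord",
    "Alignment",
    "CodonAlignment",
    "read_fasta",
    "write_fasta",
    "strip_gap_columns",
    "translate",
]

NUCLEOTIDE_ALPHABET = frozenset("ACGTN-")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X-")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)

Kind = Literal["nucleotide", "protein"]


class AlignmentError(ValueError):
    """An alignment invariant (equal lengths, frame, gaps, stops) is violated."""


class InputError(ValueError):
    """Malformed or empty input data."""


@dataclasses.dataclass(frozen=True)
class SequenceRecord:
    """A single labelled sequence.  ``seq`` is stored uppercase."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record requires a non-empty id")
        if not self.seq:
            raise InputError(f"sequence {self.id!r} is empty")
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class Alignment:
    """An ordered collection of equal-length sequences.

    Parameters
    ----------
    records:
        The sequences, in input order.  Ids must be unique.
    kind:
        ``"nucleotide"`` (alphabet ACGTN-) or ``"protein"``
        (20 amino acids plus ``*``, ``X`` and ``-``).
    """

    records: tuple[SequenceRecord, ...]
    kind: Kind = "nucleotide"

    def __post_init__(self) -> None:
        records = tuple(self.records)
        object.__setattr__(self, "records", records)
        if not records:
            raise InputError("alignment requires at least one sequence")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sequence ids: {dup}")
        lengths = {len(r) for r in records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged sequence lengths: {sorted(lengths)}")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == "nucleotide" else PROTEIN_ALPHABET
        for r in records:
            bad = set(r.seq) - alphabet
            if bad:
                raise InputError(
                    f"sequence {r.id!r} contains characters outside the "
                    f"{self.kind} alphabet: {sorted(bad)}"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, key: int | str) -> SequenceRecord:
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)

    def columns(self) -> Iterator[str]:
        for j in range(self.length):
            yield self.column(j)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Return the sub-alignment restricted to ``ids`` (in given order)."""
        return Alignment(tuple(self[i] for i in ids), kind=self.kind)

    def has_gaps(self) -> bool:
        return any("-" in r.seq for r in self.records)


@dataclasses.dataclass(frozen=True)
class CodonAlignment:
    """An in-frame, gap-free nucleotide alignment.

    ``frame_offset`` is the 0-based column where codon 1 starts; columns
    before it are ignored by codon statistics, as are trailing columns
    that do not fill a codon... they are rejected instead: after the
    offset the length must be divisible by 3.

    Internal stop codons are an error unless ``allow_stops`` is set;
    truncated or pseudogenised alleles carrying premature stops can then
    still be loaded, but codon statistics treat stop-containing codons as
    missing.
    """

    alignment: Alignment
    frame_offset: int = 0
    allow_stops: bool = False

    def __post_init__(self) -> None:
        if self.alignment.kind != "nucleotide":
            raise AlignmentError("codon alignment requires nucleotide sequences")
        if self.frame_offset < 0 or self.frame_offset >= self.alignment.length:
            raise AlignmentError(f"frame offset {self.frame_offset} out of range")
        span = self.alignment.length - self.frame_offset
        if span % 3 != 0:
            raise AlignmentError(
                f"alignment length {self.alignment.length} minus frame offset "
                f"{self.frame_offset} is not divisible by 3"
            )
        if not self.allow_stops:
            for r in self.alignment:
                codons = _codons_of(r.seq, self.frame_offset)
                for k, codon in enumerate(codons[:-1]):  # terminal stop is fine
                    if codon in STOP_CODONS:
                        raise AlignmentError(
                            f"internal stop codon in {r.id!r} at codon {k + 1}"
                        )

    @property
    def n(self) -> int:
        return self.alignment.n

    @property
    def n_codons(self) -> int:
        return (self.alignment.length - self.frame_offset) // 3

    @property
    def ids(self) -> tuple[str, ...]:
        return self.alignment.ids

    def codons(self, seq_index: int) -> list[str]:
        """Codon list for one sequence (frame applied)."""
        return _codons_of(self.alignment.records[seq_index].seq, self.frame_offset)

    def codon_column(self, k: int) -> list[str]:
        """The k-th codon across all sequences."""
        j = self.frame_offset + 3 * k
        return [r.seq[j : j + 3] for r in self.alignment.records]


def _codons_of(seq: str, offset: int) -> list[str]:
    coding = seq[offset:]
    return [coding[i : i + 3] for i in range(0, len(coding), 3)]


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, kind: Kind = "nucleotide") -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Records are returned in file order and uppercased; gap characters are
    preserved.  Ragged lengths raise :class:`AlignmentError`, an empty
    file raises :class:`InputError`.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [
        SequenceRecord(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise InputError(f"no FASTA records in {path}")
    return Alignment(tuple(records), kind=kind)


def write_fasta(aln: Alignment, path: str | Path, width: int = 80) -> None:
    """Write an alignment as FASTA with ``width``-column line wrapping."""
    path = Path(path)
    with path.open("w") as fh:
        for r in aln:
            fh.write(f">{r.id}\n")
            for i in range(0, len(r.seq), width):
                fh.write(r.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gap handling and translation
# ---------------------------------------------------------------------------

def strip_gap_columns(aln: Alignment) -> tuple[Alignment, list[int]]:
    """Remove every column containing at least one gap (complete deletion).

    Returns the stripped alignment together with the list of retained
    original column indices, so downstream positions can be traced back
    to the input coordinate system.  Raises :class:`AlignmentError` if no
    column survives.
    """
    kept = [j for j in range(aln.length) if "-" not in aln.column(j)]
    if not kept:
        raise AlignmentError("all columns contain gaps; nothing left to analyse")
    records = tuple(
        SequenceRecord(r.id, "".join(r.seq[j] for j in kept)) for r in aln
    )
    return Alignment(records, kind=aln.kind), kept


def translate_codon(codon: str) -> str:
    """Translate one codon with the standard genetic code.

    Codons containing ``N`` translate to ``X``; stop codons to ``*``.
    """
    if codon in STOP_CODONS:
        return "*"
    aa = _STANDARD_TABLE.forward_table.get(codon)
    if aa is not None:
        return aa
    if "N" in codon:
        return "X"
    raise InputError(f"cannot translate codon {codon!r}")


def translate(codon_aln: CodonAlignment) -> Alignment:
    """Translate an in-frame codon alignment to a protein alignment.

    A stop in the terminal codon is dropped (for all sequences, so the
    protein alignment stays rectangular); an internal stop raises
    :class:`AlignmentError` naming the sequence and codon index.
    """
    n_codons = codon_aln.n_codons
    last = codon_aln.codon_column(n_codons - 1) if n_codons else []
    drop_terminal = any(c in STOP_CODONS for c in last)
    if drop_terminal and not all(c in STOP_CODONS for c in last):
        raise AlignmentError(
            "terminal codon is a stop in some sequences but not all; "
            "trim the alignment before translating"
        )
    out = []
    for i, rec in enumerate(codon_aln.alignment):
        aas = []
        codons = codon_aln.codons(i)
        if drop_terminal:
            codons = codons[:-1]
        for k, codon in enumerate(codons):
            if "-" in codon:
                raise AlignmentError(
                    f"gap inside codon {k + 1} of {rec.id!r}; strip gap columns first"
                )
            aa = translate_codon(codon)
            if aa == "*":
                raise AlignmentError(
                    f"internal stop codon in {rec.id!r} at codon {k + 1}"
                )
            aas.append(aa)
        out.append(SequenceRecord(rec.id, "".join(aas)))
    return Alignment(tuple(out), kind="protein")
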