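"""On-disk formats used by the pipeline: FASTA, FASTQ (Phred+33) and
12-column tab-separated alignment hit tables (the BLAST tabular dialect).

Internal coordinates are 0-based half-open throughout the package; hit
tables keep the 1-based inclusive convention of the 12-column standard,
converted only here at the I/O boundary (i.e. stored as parsed, since the
fields are carried verbatim downstream).

Sequences are upper-cased on read and 'U' is mapped to 'T' so a single
canonical nucleotide alphabet {A,C,G,T,N} flows through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PathLike = Union[str, Path]

__all__ = [
    "FormatError",
    "SequenceRecord",
    "HitRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_hit_table",
    "write_hit_table",
]


class FormatError(ValueError):
    """A file violates its declared format."""


_CANON = str.maketrans("uU", "tT")


def _canonical(seq: str) -> str:
    return seq.translate(_CANON).upper()


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA/FASTQ entry.

    ``quality``, when present, is a Phred+33 string of the same length as
    ``sequence``.
    """

    id: str
    sequence: str
    description: str = ""
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid record id: {self.id!r}")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class HitRecord:
    """One row of a 12-column tabular alignment hit file.

    Query/subject coordinates are 1-based inclusive, as in the format.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: "
                f"pct_identity {self.pct_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise FormatError(
                f"hit {self.query_id}->{self.subject_id}: negative e-value"
            )


def read_fasta(path: PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, preserving file order.

    Multi-line sequences are concatenated; the description is the header
    text after the first whitespace. An empty file yields an empty list; a
    header with no sequence is a :class:`FormatError`.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = _canonical(str(rec.seq))
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has no sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def read_fastq(path: PathLike) -> list[SequenceRecord]:
    """Read a 4-line-per-record FASTQ file.

    Truncated final records and sequence/quality length mismatches raise
    :class:`FormatError` naming the record index (1-based).
    """
    records: list[SequenceRecord] = []
    with open(path) as fh:
        it = FastqGeneralIterator(fh)
        index = 0
        while True:
            index += 1
            try:
                title, seq, qual = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise FormatError(f"FASTQ record {index}: {exc}") from exc
            parts = title.split(None, 1)
            records.append(
                SequenceRecord(
                    id=parts[0],
                    sequence=_canonical(seq),
                    description=parts[1] if len(parts) > 1 else "",
                    quality=qual,
                )
            )
    return records


def iter_fastq_pairs(
    path_r1: PathLike, path_r2: PathLike
) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    """Iterate synchronized mate pairs from two FASTQ files."""
    with open(path_r1) as fh1, open(path_r2) as fh2:
        it1, it2 = FastqGeneralIterator(fh1), FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2, strict=True):
            yield (
                SequenceRecord(t1.split(None, 1)[0], _canonical(s1), quality=q1),
                SequenceRecord(t2.split(None, 1)[0], _canonical(s2), quality=q2),
            )


def write_fastq(records: Iterable[SequenceRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.quality is None:
                raise FormatError(f"record {rec.id!r} has no quality string")
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{rec.quality}\n")


_HIT_FIELDS = 12


def read_hit_table(path: PathLike) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit table; '#' comment lines skipped."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _HIT_FIELDS:
                raise FormatError(
                    f"line {lineno}: expected {_HIT_FIELDS} columns, got {len(cols)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        aln_length=int(cols[3]),
                        mismatches=int(cols[4]),
                        gap_opens=int(cols[5]),
                        q_start=int(cols[6]),
                        q_end=int(cols[7]),
                        s_start=int(cols[8]),
                        s_end=int(cols[9]),
                        evalue=float(cols[10]),
                        bitscore=float(cols[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return hits


def _num(x: float) -> str:
    # repr round-trips floats; integers print without trailing '.0'
    return str(int(x)) if float(x).is_integer() and abs(x) < 1e15 else repr(float(x))


def write_hit_table(hits: Iterable[HitRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        _num(h.pct_identity),
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        _num(h.evalue),
                        _num(h.bitscore),
                    ]
                )
                + "\n"
            )


_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the canonical {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP)[::-1]
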