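"""Plain-text I/O for the formats the pipeline exchanges.

Assembled transcriptome sequences travel as FASTA, with the number of reads
that constitute each contig or singleton carried in the header as a
``reads=<n>`` token (assemblers report this only in their own log formats,
so the pipeline makes it explicit).  Pairwise similarity searches are
exchanged in the 12-column tabular hit format (the BLAST ``outfmt 6``
dialect), so externally computed searches can be dropped in for the internal
one.  Functional annotations are a two-column TSV of record id and term id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")
_READS_TOKEN = re.compile(r"(?:^|\s)reads=(\S+)")


@dataclass
class SequenceRecord:
    """One assembled contig or unassembled singleton read.

    Parameters
    ----------
    id : str
        Record identifier, unique within one species' dataset.
    species : str
        Species label.
    sequence : str
        DNA over the alphabet ``ACGTN`` (upper-cased on construction).
    read_count : int
        Number of reads constituting the record; ``1`` marks a singleton,
        ``>= 2`` a contig.  ``kind`` is derived accordingly.
    """

    id: str
    species: str
    sequence: str
    read_count: int
    kind: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.id}: invalid characters {sorted(bad)}; only ACGTN accepted"
            )
        if int(self.read_count) != self.read_count or self.read_count < 1:
            raise ValueError(f"{self.id}: read_count must be a positive integer")
        self.read_count = int(self.read_count)
        self.kind = "singleton" if self.read_count == 1 else "contig"

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class HitRecord:
    """One line of a 12-column tabular similarity search result.

    Coordinates are 1-based inclusive.  Hits on the minus strand carry
    ``s_start > s_end``, as in the tabular dialect.
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
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must lie in [0, 100]")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


#: record id -> set of term ids
AnnotationMap = dict


def read_fasta(path, species: str, strict: bool = True) -> list[SequenceRecord]:
    """Read a FASTA file whose headers carry ``reads=<n>`` tokens.

    In strict mode a missing or unparseable token is an error; in lenient
    mode the record defaults to ``read_count = 1`` with a logged warning.
    Duplicate ids and non-ACGTN characters are always errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _READS_TOKEN.search(rec.description)
        read_count = None
        if m is not None:
            try:
                read_count = int(m.group(1))
            except ValueError:
                read_count = None
        if read_count is None:
            if strict:
                raise ValueError(
                    f"{path}: record {rec.id!r} has no parseable reads=<n> token"
                )
            logger.warning(
                "%s: record %s has no reads=<n> token; defaulting to 1", path, rec.id
            )
            read_count = 1
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, species, str(rec.seq), read_count))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, wrap_width: int = 60) -> None:
    """Write records as FASTA with ``reads=<n>`` headers, wrapping sequence lines."""
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id} reads={rec.read_count}\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap_width):
                fh.write(seq[i : i + wrap_width] + "\n")


def read_hit_table(path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file; order is preserved."""
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    """Write hits in the 12-column tabular dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:g}",
                        f"{h.bitscore:g}",
                    ]
                )
                + "\n"
            )


def read_annotation_map(path) -> AnnotationMap:
    """Read a two-column TSV of (record id, term id) into id -> set of terms."""
    mapping: AnnotationMap = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            rec_id, term = fields
            if not rec_id or not term:
                raise ValueError(f"{path}:{lineno}: empty record id or term id")
            mapping.setdefault(rec_id, set()).add(term)
    return mapping


def write_annotation_map(mapping: Mapping[str, set], path) -> None:
    with open(path, "w") as fh:
        for rec_id in sorted(mapping):
            for term in sorted(mapping[rec_id]):
                fh.write(f"{rec_id}\t{term}\n")
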