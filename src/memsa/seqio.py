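"""FASTA and topology-annotation I/O.

Reading and writing go through Bio.SeqIO; this module adds the validation
the aligner relies on (unique ids, strict amino-acid alphabet, gap handling)
and the 1-based -> 0-based coordinate conversion for annotation files.
All internal coordinates are 0-based half-open; conversion happens only here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO, Union

from Bio import SeqIO

from .topology import LABELS, TopologyAnnotation, TopologySegment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"


@dataclass(frozen=True)
class SequenceRecord:
    """An identified, unaligned protein sequence.

    ``residues`` is uppercase over the 20 amino acids plus X, with no gaps
    or whitespace; ``id`` is a non-empty whitespace-free token.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, c in enumerate(self.residues):
            if c not in ALPHABET:
                raise ValueError(
                    f"sequence {self.id!r}: invalid residue {c!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A gapped, equal-width set of rows with provenance to input records.

    ``column_labels``, when present, tags each column ``TM``, ``loop`` or
    ``mixed`` (columns introduced while merging off-class sequences).
    """

    rows: list[tuple[str, str]]
    column_labels: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        width = len(self.rows[0][1])
        for rid, row in self.rows:
            if len(row) != width:
                raise ValueError(
                    f"row {rid!r} has width {len(row)}, expected {width}"
                )
        if self.column_labels is not None and len(self.column_labels) != width:
            raise ValueError("column_labels length != alignment width")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, record_id: str) -> str:
        for rid, row in self.rows:
            if rid == record_id:
                return row
        raise KeyError(record_id)

    def degapped(self, record_id: str) -> str:
        return self.row(record_id).replace(GAP, "")

    def check_roundtrip(self, records: Iterable[SequenceRecord]) -> None:
        """Assert degapping each row reproduces its input record exactly."""
        by_id = {r.id: r.residues for r in records}
        for rid, row in self.rows:
            if row.replace(GAP, "") != by_id[rid]:
                raise AssertionError(
                    f"round-trip violation: degapped row for {rid!r} does not "
                    f"match the input residues"
                )

    def strip_all_gap_columns(self) -> "Alignment":
        keep = [
            j
            for j in range(self.width)
            if any(row[j] != GAP for _, row in self.rows)
        ]
        rows = [(rid, "".join(row[j] for j in keep)) for rid, row in self.rows]
        labels = (
            [self.column_labels[j] for j in keep]
            if self.column_labels is not None
            else None
        )
        return Alignment(rows, labels)


def _as_handle(source: Union[str, TextIO]) -> TextIO:
    return io.StringIO(source) if isinstance(source, str) else source


def read_fasta(source: Union[str, TextIO]) -> list[SequenceRecord]:
    """Parse unaligned FASTA into validated records.

    Residues are uppercased, a terminal ``*`` stop is stripped, and gaps are
    rejected.  Duplicate ids and out-of-alphabet residues raise ``ValueError``.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_as_handle(source), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        description = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(rec.id, seq, description))
    if not records:
        raise ValueError("no sequences in input")
    return records


def read_fasta_alignment(source: Union[str, TextIO]) -> Alignment:
    """Parse aligned FASTA; ``.`` gaps are normalized to ``-``."""
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_as_handle(source), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        row = str(rec.seq).upper().replace(".", GAP)
        for pos, c in enumerate(row):
            if c != GAP and c not in ALPHABET:
                raise ValueError(
                    f"row {rec.id!r}: invalid symbol {c!r} at column {pos + 1}"
                )
        rows.append((rec.id, row))
    if not rows:
        raise ValueError("no sequences in input")
    return Alignment(rows)


def write_fasta(
    data: Union[Iterable[SequenceRecord], Alignment], line_width: int = 60
) -> str:
    """Render records or an alignment as FASTA text."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    if isinstance(data, Alignment):
        items = [(rid, row, "") for rid, row in data.rows]
    else:
        items = [(r.id, r.residues, r.description) for r in data]
    if not items:
        raise ValueError("nothing to write")
    out: list[str] = []
    for rid, seq, desc in items:
        header = f">{rid} {desc}".rstrip()
        out.append(header)
        for i in range(0, len(seq), line_width):
            out.append(seq[i : i + line_width])
    return "\n".join(out) + "\n"


def parse_topology_annotation(
    source: Union[str, TextIO],
) -> dict[str, TopologyAnnotation]:
    """Parse long-format topology lines ``<id> <program> <label> <start> <end>``.

    Coordinates in the file are 1-based inclusive (the TMHMM convention);
    they are converted to 0-based half-open here.  Per id, segments must
    start at residue 1 and tile the sequence contiguously.
    """
    per_id: dict[str, list[TopologySegment]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(_as_handle(source), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 5:
            raise ValueError(f"line {lineno}: expected 5 fields, got {len(fields)}")
        rid, _program, label, start_s, end_s = fields
        if label not in LABELS:
            raise ValueError(f"line {lineno}: unknown label {label!r}")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"line {lineno}: non-integer coordinates") from exc
        if not 1 <= start <= end:
            raise ValueError(f"line {lineno}: invalid range {start}-{end}")
        if rid not in per_id:
            per_id[rid] = []
            order.append(rid)
        per_id[rid].append(TopologySegment(label, start - 1, end))

    out: dict[str, TopologyAnnotation] = {}
    for rid in order:
        segments = sorted(per_id[rid], key=lambda s: s.start)
        if segments[0].start != 0:
            raise ValueError(f"{rid!r}: annotation does not start at residue 1")
        for prev, cur in zip(segments, segments[1:]):
            if cur.start != prev.end:
                raise ValueError(
                    f"{rid!r}: coverage gap or overlap at residue {prev.end + 1}"
                )
        out[rid] = TopologyAnnotation.from_segments(rid, segments)
    return out


def write_topology_annotation(
    annotations: Mapping[str, TopologyAnnotation], program: str = "memsa"
) -> str:
    """Render annotations in the long format read by parse_topology_annotation."""
    lines = []
    for rid, ann in annotations.items():
        for seg in ann.segments:
            lines.append(f"{rid}\t{program}\t{seg.label}\t{seg.start + 1}\t{seg.end}")
    return "\n".join(lines) + ("\n" if lines else "")
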