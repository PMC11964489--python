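"""Signal-to-sequence alignment containers: PAF with ``ss`` tags, and SAM
carrying basecaller move tables.

PAF convention for signal alignments: the *query* is the raw signal (qlen =
number of samples, qstart/qend the aligned sample span) and the *target* is
the sequence (read or reference).  The run-length alignment itself travels
in an ``ss:Z:`` auxiliary tag.

SAM move-table dialect: an auxiliary ``mv:B,c`` byte array whose first
element is the neural-net stride and the remainder the per-step 0/1 moves;
the number of samples trimmed before the first step is taken from the
``ts:i`` tag when present, else 0.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .errors import FormatError
from .ss import MoveTable, SsAlignment, move_table_to_ss, parse_ss, serialize_ss

__all__ = [
    "PafRecord",
    "read_paf",
    "write_paf",
    "read_sam_move_tables",
]


@dataclass
class PafRecord:
    """One PAF line carrying a signal-to-sequence alignment."""

    read_id: str
    signal_len: int
    target_name: str
    target_len: int
    alignment: SsAlignment
    mapq: int = 60

    def to_line(self) -> str:
        aln = self.alignment
        sig_end = aln.signal_start + aln.n_signal
        seq_end = aln.seq_start + aln.n_bases
        cols = [
            self.read_id,
            str(self.signal_len),
            str(aln.signal_start),
            str(sig_end),
            "+",
            self.target_name,
            str(self.target_len),
            str(aln.seq_start),
            str(seq_end),
            str(aln.n_bases),
            str(sig_end - aln.signal_start),
            str(self.mapq),
            f"ss:Z:{serialize_ss(aln.ops)}",
        ]
        return "\t".join(cols)


def read_paf(path: str | Path | TextIO) -> Iterator[PafRecord]:
    """Stream PAF records that carry an ``ss:Z:`` tag.

    Lines without the tag raise :class:`FormatError`; the pipeline has no
    use for an alignment whose segmentation is unknown.
    """
    fh = path if isinstance(path, io.TextIOBase) else open(path)
    close = not isinstance(path, io.TextIOBase)
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 13:
                raise FormatError(f"PAF line {lineno}: fewer than 13 columns")
            ss_text = None
            for tag in fields[12:]:
                if tag.startswith("ss:Z:"):
                    ss_text = tag[5:]
                    break
            if ss_text is None:
                raise FormatError(f"PAF line {lineno}: no ss:Z: tag")
            aln = SsAlignment(
                ops=parse_ss(ss_text),
                signal_start=int(fields[2]),
                seq_start=int(fields[7]),
                seq_is_reference=fields[0] != fields[5],
            )
            yield PafRecord(
                read_id=fields[0],
                signal_len=int(fields[1]),
                target_name=fields[5],
                target_len=int(fields[6]),
                alignment=aln,
                mapq=int(fields[11]),
            )
    finally:
        if close:
            fh.close()


def write_paf(records: Iterable[PafRecord], path: str | Path | TextIO) -> None:
    fh = path if isinstance(path, io.TextIOBase) else open(path, "w")
    close = not isinstance(path, io.TextIOBase)
    try:
        for rec in records:
            fh.write(rec.to_line() + "\n")
    finally:
        if close:
            fh.close()


def read_sam_move_tables(
    path: str | Path,
) -> Iterator[tuple[str, MoveTable, SsAlignment, str | None]]:
    """Yield ``(read_id, move_table, ss_alignment, sequence)`` from a SAM file.

    Unmapped/secondary records are included (move tables describe the read,
    not a mapping); records without an ``mv`` tag are skipped.
    """
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if not rec.has_tag("mv"):
                continue
            mv_array = list(rec.get_tag("mv"))
            if len(mv_array) < 2:
                raise FormatError(f"read {rec.query_name}: mv tag too short")
            stride, moves = int(mv_array[0]), [int(v) for v in mv_array[1:]]
            trim = int(rec.get_tag("ts")) if rec.has_tag("ts") else 0
            mv = MoveTable(stride=stride, moves=moves, trim_offset=trim)
            signal_len = trim + stride * len(moves)
            aln = move_table_to_ss(mv, signal_len)
            yield rec.query_name, mv, aln, rec.query_sequence
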