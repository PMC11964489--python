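"""Raw-signal records and their on-disk container.

Signals are exchanged in the ASCII SLOW5 dialect: a plain tab-separated
text file with ``#``/``@`` header lines, a ``#``-prefixed column header, and
one record per line with the raw samples comma-separated.  This covers the
.slow5 text files emitted by the usual conversion tools and doubles as the
package's self-contained fixture format.  Binary BLOW5 is not read — convert
to ASCII SLOW5 first.

The ADC-to-picoampere conversion follows the container's standard header
semantics::

    pA = (raw + offset) * range / digitisation
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np

from .errors import FormatError

__all__ = [
    "ReadRecord",
    "raw_to_pa",
    "load_signals",
    "write_signals",
    "attach_sequences",
    "read_sequences",
]

_VALID_BASES = set("ACGTUN")

_REQUIRED_COLUMNS = (
    "read_id",
    "digitisation",
    "offset",
    "range",
    "sampling_rate",
    "raw_signal",
)


@dataclass
class ReadRecord:
    """One read's raw signal plus the calibration needed to reach pA."""

    read_id: str
    raw: np.ndarray  # integer ADC samples
    digitisation: float
    range_pA: float
    offset: float
    sampling_rate: float
    sequence: str | None = None  # written 5'->3'

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw)
        if self.raw.size == 0:
            raise ValueError("raw signal is empty")
        if self.digitisation <= 0 or self.range_pA <= 0 or self.sampling_rate <= 0:
            raise ValueError("digitisation, range and sampling_rate must be > 0")
        if self.sequence is not None:
            self.sequence = self.sequence.upper().replace("U", "T")
            bad = set(self.sequence) - _VALID_BASES
            if bad:
                raise ValueError(f"sequence contains invalid characters {bad}")

    def to_pa(self) -> np.ndarray:
        return raw_to_pa(self)


def raw_to_pa(rec: ReadRecord) -> np.ndarray:
    """Convert ADC units to picoamperes using the record's calibration."""
    return (rec.raw.astype(np.float64) + rec.offset) * (
        rec.range_pA / rec.digitisation
    )


def _open(path: str | Path | TextIO, mode: str = "r") -> TextIO:
    if isinstance(path, io.TextIOBase):
        return path
    return open(path, mode)


def load_signals(path: str | Path | TextIO) -> Iterator[ReadRecord]:
    """Stream :class:`ReadRecord` objects from an ASCII SLOW5 file.

    Header lines starting with ``@`` (attributes) or ``#`` (version, types)
    are skipped except the last ``#`` line before the records, which names
    the columns.  Raises :class:`FormatError` if the calibration columns are
    missing or a row is ragged.
    """
    fh = _open(path)
    close = not isinstance(path, io.TextIOBase)
    try:
        if _peek_binary(fh):
            raise FormatError(
                "input looks like binary BLOW5; convert to ASCII SLOW5 first"
            )
        columns: list[str] | None = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("@"):
                continue
            if line.startswith("#"):
                fields = line[1:].split("\t")
                if "read_id" in fields:
                    columns = fields
                continue
            if columns is None:
                raise FormatError(
                    "no '#read_id ...' column header before data rows"
                )
            missing = [c for c in _REQUIRED_COLUMNS if c not in columns]
            if missing:
                raise FormatError(f"missing calibration columns: {missing}")
            values = line.split("\t")
            if len(values) != len(columns):
                raise FormatError(
                    f"line {lineno}: {len(values)} fields, expected {len(columns)}"
                )
            row = dict(zip(columns, values))
            try:
                raw = np.array(
                    [int(v) for v in row["raw_signal"].split(",") if v != ""],
                    dtype=np.int32,
                )
            except ValueError as exc:
                raise FormatError(f"line {lineno}: bad raw_signal: {exc}") from exc
            yield ReadRecord(
                read_id=row["read_id"],
                raw=raw,
                digitisation=float(row["digitisation"]),
                range_pA=float(row["range"]),
                offset=float(row["offset"]),
                sampling_rate=float(row["sampling_rate"]),
            )
    finally:
        if close:
            fh.close()


def _peek_binary(fh: TextIO) -> bool:
    try:
        pos = fh.tell()
        head = fh.read(8)
        fh.seek(pos)
    except (OSError, UnicodeDecodeError):
        return True
    return head.startswith("BLOW5")


def write_signals(records: Iterable[ReadRecord], path: str | Path | TextIO) -> None:
    """Write records as ASCII SLOW5; round-trips through :func:`load_signals`."""
    fh = _open(path, "w")
    close = not isinstance(path, io.TextIOBase)
    try:
        fh.write("#slow5_version\t0.2.0\n")
        fh.write("#num_read_groups\t1\n")
        fh.write(
            "#read_id\tread_group\tdigitisation\toffset\trange\t"
            "sampling_rate\tlen_raw_signal\traw_signal\n"
        )
        for rec in records:
            raw = ",".join(str(int(v)) for v in rec.raw)
            fh.write(
                f"{rec.read_id}\t0\t{rec.digitisation!r}\t{rec.offset!r}\t"
                f"{rec.range_pA!r}\t{rec.sampling_rate!r}\t{rec.raw.size}\t{raw}\n"
            )
    finally:
        if close:
            fh.close()


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read FASTA or FASTQ into ``{read_id: sequence}`` (U mapped to T)."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return {
        r.id: str(r.seq).upper().replace("U", "T")
        for r in SeqIO.parse(str(path), fmt)
    }


def attach_sequences(
    records: Iterable[ReadRecord], sequences: dict[str, str]
) -> Iterator[ReadRecord]:
    """Attach basecalled/reference sequences to records by read id.

    Records without a sequence are passed through unchanged (the sampler
    skips them and counts the skip).
    """
    for rec in records:
        seq = sequences.get(rec.read_id)
        if seq is not None:
            rec.sequence = seq.upper().replace("U", "T")
        yield rec
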