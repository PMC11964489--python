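"""The ``ss`` run-length alignment format.

An ``ss`` string is a compact encoding of a signal-to-sequence alignment as
a sequence of operations:

* a bare integer ``n`` — a *match* run: ``n`` signal samples assigned to the
  current base (the base cursor then advances by one);
* ``nD`` — a *deletion*: ``n`` bases with no signal (base cursor advances by
  ``n``);
* ``nI`` — an *insertion*: ``n`` signal samples not assigned to any base
  (signal cursor advances by ``n``).

For example ``"7,2D3,4I,5"`` reads as seven signal matches on the first
base, two deleted bases, three matches, four inserted samples, and five
final matches.  Commas between operations are optional on input; the
serializer emits a comma after every match run except the last operation,
reproducing the upstream tools' style.

Coordinates are 0-based and signal intervals are half-open.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .errors import BoundsError, SsParseError

__all__ = [
    "OpKind",
    "SsOp",
    "SsAlignment",
    "MoveTable",
    "parse_ss",
    "serialize_ss",
    "ss_to_segments",
    "move_table_to_ss",
]


class OpKind(enum.Enum):
    MATCH = "M"
    DELETION = "D"
    INSERTION = "I"


@dataclass(frozen=True)
class SsOp:
    kind: OpKind
    length: int  # samples for MATCH/INSERTION, bases for DELETION

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"ss op length must be positive, got {self.length}")


@dataclass
class SsAlignment:
    """A parsed signal-to-sequence alignment anchored in both coordinates."""

    ops: list[SsOp]
    signal_start: int = 0
    seq_start: int = 0
    seq_is_reference: bool = False

    @property
    def n_signal(self) -> int:
        """Total signal samples consumed (matches + insertions)."""
        return sum(
            op.length for op in self.ops if op.kind is not OpKind.DELETION
        )

    @property
    def n_bases(self) -> int:
        """Total bases traversed (one per match run + deletion lengths)."""
        return sum(
            1 if op.kind is OpKind.MATCH else op.length
            for op in self.ops
            if op.kind is not OpKind.INSERTION
        )

    def to_string(self) -> str:
        return serialize_ss(self.ops)


@dataclass
class MoveTable:
    """Basecaller move table: per-stride 0/1 flags marking new-base steps."""

    stride: int
    moves: list[int] = field(default_factory=list)
    trim_offset: int = 0  # raw samples trimmed before the first step

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError(f"stride must be >= 1, got {self.stride}")
        if any(m not in (0, 1) for m in self.moves):
            raise ValueError("moves must be 0/1 flags")


def parse_ss(text: str) -> list[SsOp]:
    """Parse an ss operation string into an ordered operation list.

    Commas are accepted (and ignored) between any two tokens, including a
    trailing comma.  A malformed or zero-length token raises
    :class:`SsParseError` naming the byte offset.
    """
    ops: list[SsOp] = []
    i, n = 0, len(text)
    while i < n:
        if text[i] == ",":
            i += 1
            continue
        if not text[i].isdigit():
            raise SsParseError(f"expected digit, found {text[i]!r}", i)
        start = i
        while i < n and text[i].isdigit():
            i += 1
        length = int(text[start:i])
        if length == 0:
            raise SsParseError("zero-length operation", start)
        if i < n and text[i] in "DI":
            kind = OpKind.DELETION if text[i] == "D" else OpKind.INSERTION
            i += 1
        else:
            kind = OpKind.MATCH
        ops.append(SsOp(kind, length))
    return ops


def serialize_ss(ops: Iterable[SsOp]) -> str:
    """Inverse of :func:`parse_ss`: ``parse_ss(serialize_ss(ops)) == ops``."""
    ops = list(ops)
    parts: list[str] = []
    for idx, op in enumerate(ops):
        sep = "," if idx < len(ops) - 1 else ""
        if op.kind is OpKind.MATCH:
            parts.append(f"{op.length}{sep}")
        elif op.kind is OpKind.DELETION:
            parts.append(f"{op.length}D")  # letter already delimits
        else:
            parts.append(f"{op.length}I{sep}")
    return "".join(parts)


def ss_to_segments(
    aln: SsAlignment, signal_len: int, seq_len: int
) -> list[tuple[int, tuple[int, int]]]:
    """Expand an alignment into per-base signal segments.

    Returns ``(base_index, (start, end))`` pairs, one per base covered by a
    match run, with half-open 0-based signal intervals.  Deleted bases get
    no segment; inserted samples are skipped.  Raises :class:`BoundsError`
    if a cursor runs past ``signal_len`` or ``seq_len``.
    """
    sig = aln.signal_start
    base = aln.seq_start
    out: list[tuple[int, tuple[int, int]]] = []
    for op in aln.ops:
        if op.kind is OpKind.MATCH:
            if sig + op.length > signal_len:
                raise BoundsError(
                    f"match run of {op.length} at sample {sig} exceeds "
                    f"signal length {signal_len}"
                )
            if base >= seq_len:
                raise BoundsError(
                    f"base cursor {base} exceeds sequence length {seq_len}"
                )
            out.append((base, (sig, sig + op.length)))
            sig += op.length
            base += 1
        elif op.kind is OpKind.DELETION:
            base += op.length
            if base > seq_len:
                raise BoundsError(
                    f"deletion run exceeds sequence length {seq_len}"
                )
        else:  # INSERTION
            sig += op.length
            if sig > signal_len:
                raise BoundsError(
                    f"insertion run exceeds signal length {signal_len}"
                )
    return out


def move_table_to_ss(mv: MoveTable, signal_len: int) -> SsAlignment:
    """Convert a move table to an ss alignment of pure match runs.

    Each maximal run of steps beginning at a 1-move becomes one match of
    ``run_length * stride`` samples, so the total signal consumed equals
    ``stride * len(moves)``.
    """
    if not mv.moves:
        raise ValueError("move table is empty")
    if mv.moves[0] != 1:
        raise ValueError("first move must be 1 (a base is emitted at step 0)")
    if mv.stride * len(mv.moves) + mv.trim_offset > signal_len:
        raise BoundsError(
            f"move table spans {mv.stride * len(mv.moves)} samples after "
            f"trim {mv.trim_offset}, but signal has only {signal_len}"
        )
    ops: list[SsOp] = []
    run = 0
    for m in mv.moves:
        if m == 1 and run > 0:
            ops.append(SsOp(OpKind.MATCH, run * mv.stride))
            run = 1
        else:
            run += 1
    ops.append(SsOp(OpKind.MATCH, run * mv.stride))
    return SsAlignment(ops=ops, signal_start=mv.trim_offset, seq_start=0)


def iter_segment_arrays(
    aln: SsAlignment, signal_len: int, seq_len: int
) -> Iterator[tuple[int, int, int]]:
    """Yield ``(base_index, start, end)`` without building the pair list."""
    for base, (s, e) in ss_to_segments(aln, signal_len, seq_len):
        yield base, s, e
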