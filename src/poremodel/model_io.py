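"""K-mer (pore) model tables.

A k-mer model maps every length-k subsequence to the current level expected
while it occupies the pore, optionally with a spread.  On disk the dialect
is: ``#``-prefixed header lines carrying metadata (``#k``, ``#scaling``,
``#globals`` ...), then tab-separated columns ``kmer``, ``level_mean`` and
optionally ``level_stdv``.  K-mers are written in lexicographic order.
Models over RNA alphabets are stored with U mapped to T.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, TextIO

from .errors import FormatError

__all__ = ["KmerModel", "read_model", "write_model"]

ALPHABET = ("A", "C", "G", "T")


@dataclass
class KmerModel:
    """In-memory k-mer model.

    ``levels`` maps each k-mer to ``(mean, stddev)``; ``stddev`` is ``None``
    for mean-only models (several published models carry no spread column).
    ``space`` records whether the levels are in Med-MAD-normalized units or
    real-world picoamperes.
    """

    k: int
    levels: dict[str, tuple[float, float | None]]
    space: str = "normalized"  # or "pA"
    alphabet: tuple[str, ...] = ALPHABET
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for kmer in self.levels:
            if len(kmer) != self.k:
                raise FormatError(
                    f"k-mer {kmer!r} has length {len(kmer)}, expected {self.k}"
                )
            if any(b not in self.alphabet for b in kmer):
                raise FormatError(f"k-mer {kmer!r} not over alphabet {self.alphabet}")

    @property
    def has_stddev(self) -> bool:
        return any(sd is not None for _, sd in self.levels.values())

    def completeness(self) -> float:
        """Fraction of the ``len(alphabet)**k`` possible k-mers present."""
        return len(self.levels) / len(self.alphabet) ** self.k

    def means(self) -> dict[str, float]:
        return {kmer: mu for kmer, (mu, _) in self.levels.items()}

    def __len__(self) -> int:
        return len(self.levels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KmerModel):
            return NotImplemented
        return (
            self.k == other.k
            and self.space == other.space
            and self.levels == other.levels
        )


def _open(path: str | Path | TextIO, mode: str = "r") -> tuple[TextIO, bool]:
    if isinstance(path, io.TextIOBase):
        return path, False
    return open(path, mode), True


def read_model(path: str | Path | TextIO) -> KmerModel:
    """Read a tab-separated k-mer model file.

    Raises :class:`FormatError` on ragged rows, inconsistent k, duplicate
    k-mers, or an empty table.
    """
    fh, close = _open(path)
    meta: dict[str, str] = {}
    levels: dict[str, tuple[float, float | None]] = {}
    k: int | None = None
    ncols: int | None = None
    try:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t", 1)
                if len(parts) == 2:
                    meta[parts[0]] = parts[1]
                continue
            fields = line.split("\t")
            if fields[0] == "kmer":  # optional column header
                continue
            if len(fields) not in (2, 3):
                raise FormatError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(fields)}"
                )
            if ncols is None:
                ncols = len(fields)
            elif len(fields) != ncols:
                raise FormatError(f"line {lineno}: ragged row")
            kmer = fields[0].upper().replace("U", "T")
            if k is None:
                k = len(kmer)
            elif len(kmer) != k:
                raise FormatError(
                    f"line {lineno}: k-mer {kmer!r} length {len(kmer)} != {k}"
                )
            if kmer in levels:
                raise FormatError(f"line {lineno}: duplicate k-mer {kmer!r}")
            try:
                mean = float(fields[1])
                sd = float(fields[2]) if len(fields) == 3 else None
            except ValueError as exc:
                raise FormatError(f"line {lineno}: non-numeric level") from exc
            levels[kmer] = (mean, sd)
    finally:
        if close:
            fh.close()
    if not levels:
        raise FormatError("model file contains no k-mers")
    space = meta.get("scaling", meta.get("space", "pA"))
    space = "normalized" if space in ("normalized", "med-mad") else "pA"
    return KmerModel(k=k, levels=levels, space=space, meta=meta)


def write_model(model: KmerModel, path: str | Path | TextIO) -> None:
    """Write a model; ``read_model(write_model(m)) == m`` up to metadata."""
    fh, close = _open(path, "w")
    try:
        fh.write(f"#k\t{model.k}\n")
        fh.write(f"#space\t{model.space}\n")
        for key, value in model.meta.items():
            if key in ("k", "space"):
                continue
            fh.write(f"#{key}\t{value}\n")
        with_sd = model.has_stddev
        header = "kmer\tlevel_mean" + ("\tlevel_stdv" if with_sd else "")
        fh.write(header + "\n")
        for kmer in sorted(model.levels):
            mean, sd = model.levels[kmer]
            if with_sd:
                fh.write(f"{kmer}\t{mean!r}\t{0.0 if sd is None else sd!r}\n")
            else:
                fh.write(f"{kmer}\t{mean!r}\n")
    finally:
        if close:
            fh.close()
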