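"""Event sampling: cut each read's raw signal into per-k-mer events.

Walks the signal-to-sequence alignment of a read, takes the signal segment
attributed to each base (one match run per base, as move tables provide),
labels it with the k-mer window anchored at that base, filters on dwell
time and within-event spread, and accumulates up to a cap of samples per
k-mer.

The ``move_offset`` shifts the pairing between events and k-mer windows by
whole bases: the event of alignment base ``i + move_offset`` is labelled
with the sliding window starting at base ``i``.  In RNA mode the molecule
traverses the pore 3'->5', so alignment base index 0 is the 3'-most base of
the 5'->3' sequence; traversal is over the reversed sequence and emitted
k-mer strings are re-reversed so they stay written 5'->3'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, NamedTuple

import numpy as np

from .signals import ReadRecord
from .ss import OpKind, SsAlignment, ss_to_segments

__all__ = [
    "EventSample",
    "SamplingConfig",
    "KmerAccumulator",
    "events_for_read",
    "passes_filters",
    "mask_indel_neighborhood",
    "accumulate",
]

logger = logging.getLogger(__name__)


class EventSample(NamedTuple):
    """Summary of one signal segment assigned to one k-mer."""

    mean: float  # normalized current
    stddev: float  # within-event spread, normalized units
    duration: int  # samples


@dataclass
class SamplingConfig:
    """Knobs of the sampling stage.

    Defaults mirror common direct-RNA practice: dwell bounds 20/40 samples
    around the ~30 samples/base expected at 130 bases/s and 4 kHz, a cap of
    5000 stored events per k-mer, and 2 bases skipped around indels.  The
    duration filter is strict (``min_dur < d < max_dur``); set
    ``inclusive_duration`` for closed bounds.  ``max_event_stddev`` is
    disabled when ``None``.
    """

    k: int = 5
    num_samples: int = 5000
    move_offset: int = 0
    min_dur: int = 20
    max_dur: int = 40
    max_event_stddev: float | None = None
    indel_skip: int = 2
    rna_mode: bool = False
    inclusive_duration: bool = False
    strict_cap: bool = False  # count every observation against the cap

    def __post_init__(self) -> None:
        if self.min_dur >= self.max_dur:
            raise ValueError("min_dur must be < max_dur")
        if self.num_samples < 1:
            raise ValueError("num_samples must be >= 1")
        if self.indel_skip < 0:
            raise ValueError("indel_skip must be >= 0")


def passes_filters(ev: EventSample, cfg: SamplingConfig) -> bool:
    """Dwell-time and spread filter for one event."""
    if cfg.inclusive_duration:
        ok = cfg.min_dur <= ev.duration <= cfg.max_dur
    else:
        ok = cfg.min_dur < ev.duration < cfg.max_dur
    if ok and cfg.max_event_stddev is not None:
        ok = ev.stddev <= cfg.max_event_stddev
    return ok


def mask_indel_neighborhood(aln: SsAlignment, skip: int) -> set[int]:
    """Base indices within ``skip`` of an indel, in alignment coordinates.

    Deleted bases are excluded together with ``skip`` neighbours on each
    side.  An insertion between bases ``b-1`` and ``b`` excludes the
    ``skip`` bases on each side of that boundary (none when ``skip`` is 0).
    """
    excluded: set[int] = set()
    base = aln.seq_start
    for op in aln.ops:
        if op.kind is OpKind.MATCH:
            base += 1
        elif op.kind is OpKind.DELETION:
            lo, hi = base - skip, base + op.length - 1 + skip
            excluded.update(range(lo, hi + 1))
            base += op.length
        else:  # INSERTION at boundary before `base`
            if skip > 0:
                excluded.update(range(base - skip, base + skip))
    return {b for b in excluded if b >= aln.seq_start}


def events_for_read(
    rec: ReadRecord,
    aln: SsAlignment,
    cfg: SamplingConfig,
    normalize: Callable[[np.ndarray], np.ndarray],
    excluded_bases: set[int] | None = None,
) -> Iterator[tuple[str, EventSample]]:
    """Yield ``(kmer, event)`` pairs for one read, in signal order.

    Event statistics are computed on the normalized signal (segment sums
    via cumulative arrays, so long reads cost O(signal) not O(k * signal)).
    Events whose k-mer window overlaps an excluded base, or whose window
    falls outside the sequence, are not emitted.  Reads without a sequence,
    or shorter than k, yield nothing.
    """
    seq = rec.sequence
    if seq is None or len(seq) < cfg.k:
        return
    traversal = seq[::-1] if cfg.rna_mode else seq
    n_windows = len(seq) - cfg.k + 1

    segments = ss_to_segments(aln, rec.raw.size, len(seq))
    if not segments:
        return
    base_idx = np.array([b for b, _ in segments], dtype=np.int64)
    starts = np.array([s for _, (s, _) in segments], dtype=np.int64)
    ends = np.array([e for _, (_, e) in segments], dtype=np.int64)

    normalized = np.asarray(normalize(rec.to_pa()), dtype=np.float64)
    csum = np.concatenate(([0.0], np.cumsum(normalized)))
    csum2 = np.concatenate(([0.0], np.cumsum(normalized**2)))
    dur = ends - starts
    seg_sum = csum[ends] - csum[starts]
    seg_sum2 = csum2[ends] - csum2[starts]
    means = seg_sum / dur
    var = np.maximum(seg_sum2 / dur - means**2, 0.0)
    stds = np.sqrt(var)

    excluded_bases = excluded_bases or set()
    k, off = cfg.k, cfg.move_offset
    for i in range(base_idx.size):
        b = int(base_idx[i])
        w = b - off  # window start in traversal coordinates
        if w < 0 or w >= n_windows:
            continue
        if excluded_bases and any(
            (w + j) in excluded_bases for j in range(k)
        ):
            continue
        window = traversal[w : w + k]
        kmer = window[::-1] if cfg.rna_mode else window
        yield kmer, EventSample(float(means[i]), float(stds[i]), int(dur[i]))


@dataclass
class KmerAccumulator:
    """Per-k-mer storage of filtered events, bounded by the sampling cap."""

    cfg: SamplingConfig
    samples: dict[str, list[EventSample]] = field(default_factory=dict)
    counters: dict[str, int] = field(default_factory=dict)
    n_rejected_duration: int = 0
    n_rejected_stddev: int = 0
    n_rejected_cap: int = 0

    def add(self, kmer: str, ev: EventSample) -> bool:
        cap = self.cfg.num_samples
        seen = self.counters.get(kmer, 0)
        self.counters[kmer] = seen + 1
        if self.cfg.strict_cap and seen >= cap:
            self.n_rejected_cap += 1
            return False
        if not passes_filters(ev, self.cfg):
            if self.cfg.max_event_stddev is not None and (
                ev.stddev > self.cfg.max_event_stddev
            ):
                self.n_rejected_stddev += 1
            else:
                self.n_rejected_duration += 1
            return False
        bucket = self.samples.setdefault(kmer, [])
        if not self.cfg.strict_cap and len(bucket) >= cap:
            self.n_rejected_cap += 1
            return False
        bucket.append(ev)
        return True

    def n_stored(self, kmer: str) -> int:
        return len(self.samples.get(kmer, ()))

    def completeness_report(self) -> dict[str, float]:
        """Fractions of the 4**k k-mer space at depth >=1, >=100, >=cap."""
        total = 4**self.cfg.k
        depths = [len(v) for v in self.samples.values()]
        return {
            "n_kmers_seen": float(len(depths)),
            "frac_ge_1": sum(d >= 1 for d in depths) / total,
            "frac_ge_100": sum(d >= 100 for d in depths) / total,
            "frac_at_cap": sum(d >= self.cfg.num_samples for d in depths) / total,
        }

    def dump_tsv(self, fh) -> None:
        fh.write("kmer\tmean\tstddev\tduration\n")
        for kmer in sorted(self.samples):
            for ev in self.samples[kmer]:
                fh.write(f"{kmer}\t{ev.mean!r}\t{ev.stddev!r}\t{ev.duration}\n")


def accumulate(
    stream: Iterable[tuple[str, EventSample]], cfg: SamplingConfig
) -> KmerAccumulator:
    """Drain an event stream into a capped accumulator (stream order kept)."""
    acc = KmerAccumulator(cfg=cfg)
    for kmer, ev in stream:
        acc.add(kmer, ev)
    return acc
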