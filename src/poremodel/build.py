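"""Model building: normalization, per-k-mer summaries, and the pA transform.

Per-read signals are normalized by Med-MAD scaling,

    x' = (x - median(x)) / MAD(x),   MAD(x) = median(|x - median(x)|),

with the raw MAD by default (no 1.4826 Gaussian consistency factor — the
factor only rescales an affine space that the pA transform re-fits anyway;
pass ``consistency_factor=True`` for the scaled variant).  The normalized
model is mapped back to real-world picoamperes with the dataset's global
statistics,

    pA = normalized_mean * global_stddev + global_mean,

and the model's spread column, which spans a wide range in normalized
units, is linearly rescaled onto a heuristic interval (default [2.5, 4])
that downstream event aligners expect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .errors import DegenerateSignalError, EmptyResultError
from .events import KmerAccumulator
from .model_io import KmerModel
from .signals import ReadRecord

__all__ = [
    "ScalingParams",
    "med_mad_normalize",
    "make_scaler",
    "summarize",
    "to_pa",
    "rescale_stddev",
    "estimate_globals",
]


@dataclass
class ScalingParams:
    """Global signal statistics used by the pA transform."""

    method: str = "med-mad"  # or "none"
    global_mean: float = 0.0
    global_stddev: float = 1.0


def med_mad_normalize(
    signal: np.ndarray, consistency_factor: bool = False
) -> np.ndarray:
    """Median/MAD-normalize a signal; raises on zero spread."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size < 2:
        raise DegenerateSignalError("signal too short to normalize")
    med = np.median(signal)
    mad = np.median(np.abs(signal - med))
    if consistency_factor:
        mad *= 1.4826
    if mad == 0:
        raise DegenerateSignalError("MAD is zero; degenerate signal")
    return (signal - med) / mad


def make_scaler(
    method: str = "med-mad", consistency_factor: bool = False
) -> Callable[[np.ndarray], np.ndarray]:
    """Return the per-read scaler named by ``method`` ('med-mad' or 'none')."""
    if method == "med-mad":
        return lambda x: med_mad_normalize(x, consistency_factor)
    if method == "none":
        return lambda x: np.asarray(x, dtype=np.float64)
    raise ValueError(f"unknown scaling method {method!r}")


def summarize(
    acc: KmerAccumulator,
    stat: str = "mean",
    spread: str = "mean_of_stddevs",
    min_samples: int = 1,
) -> KmerModel:
    """Collapse an accumulator into a normalized-space k-mer model.

    ``stat`` picks the per-k-mer level (mean or median of the stored event
    means); ``spread`` picks the stddev column: ``mean_of_stddevs``
    averages the within-event spreads, ``stddev_of_means`` takes the spread
    of the event means instead.  K-mers with fewer than ``min_samples``
    stored events are omitted (reported via the model's completeness).
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    if spread not in ("mean_of_stddevs", "stddev_of_means"):
        raise ValueError(f"unknown spread method {spread!r}")
    levels: dict[str, tuple[float, float | None]] = {}
    for kmer, events in acc.samples.items():
        if len(events) < min_samples:
            continue
        means = np.array([e.mean for e in events])
        level = float(np.mean(means) if stat == "mean" else np.median(means))
        if spread == "mean_of_stddevs":
            sd = float(np.mean([e.stddev for e in events]))
        else:
            sd = float(np.std(means))
        levels[kmer] = (level, sd)
    if not levels:
        raise EmptyResultError("no k-mer reached the minimum sample count")
    return KmerModel(k=acc.cfg.k, levels=levels, space="normalized")


def to_pa(model: KmerModel, params: ScalingParams) -> KmerModel:
    """Affine map of the level means from normalized space to picoamperes.

    Spreads are carried through unchanged; they are conventionally set by
    :func:`rescale_stddev`, not by this transform.
    """
    if model.space != "normalized":
        raise ValueError("model is not in normalized space")
    if params.global_stddev <= 0:
        raise ValueError("global stddev must be positive for the pA transform")
    levels = {
        kmer: (mu * params.global_stddev + params.global_mean, sd)
        for kmer, (mu, sd) in model.levels.items()
    }
    meta = dict(model.meta)
    meta["globals"] = f"mean={params.global_mean!r} stddev={params.global_stddev!r}"
    return KmerModel(k=model.k, levels=levels, space="pA", meta=meta)


def rescale_stddev(model: KmerModel, lo: float = 2.5, hi: float = 4.0) -> KmerModel:
    """Min-max map of the spread column onto ``[lo, hi]`` (order-preserving).

    All-equal spreads map to the midpoint.  Requires a spread column.
    """
    if not model.has_stddev:
        raise ValueError("model has no stddev column to rescale")
    sds = np.array([sd for _, sd in model.levels.values()], dtype=np.float64)
    smin, smax = float(sds.min()), float(sds.max())
    if smax == smin:
        mapped = {kmer: (hi + lo) / 2 for kmer in model.levels}
    else:
        scale = (hi - lo) / (smax - smin)
        mapped = {
            kmer: lo + (sd - smin) * scale
            for kmer, (_, sd) in model.levels.items()
        }
    levels = {
        kmer: (mu, mapped[kmer]) for kmer, (mu, _) in model.levels.items()
    }
    return KmerModel(k=model.k, levels=levels, space=model.space, meta=dict(model.meta))


def estimate_globals(reads: Iterable[ReadRecord]) -> ScalingParams:
    """Pooled mean/stddev of the pA signal over a read set."""
    total = 0
    s1 = 0.0
    s2 = 0.0
    for rec in reads:
        pa = rec.to_pa()
        total += pa.size
        s1 += float(pa.sum())
        s2 += float((pa**2).sum())
    if total == 0:
        raise EmptyResultError("no reads to estimate global statistics from")
    mean = s1 / total
    var = max(s2 / total - mean**2, 0.0)
    return ScalingParams(
        method="med-mad", global_mean=mean, global_stddev=float(np.sqrt(var))
    )
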