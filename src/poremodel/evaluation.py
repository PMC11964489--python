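"""Model and alignment evaluation.

Two instruments: (i) the Pearson correlation between the level means of two
k-mer models over their shared k-mers (models of different k are first
collapsed to a common register), and (ii) a tolerance-based F1 score that
compares two one-to-one signal-point-to-base mappings.  A query point
mapped within ``tolerance`` bases of the truth's base is a true positive; a
point the query maps where the truth does not, or maps too far away, is a
false positive; a truth-mapped point the query leaves unmapped is a false
negative; points unmapped in both are true negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model_io import KmerModel
from .ss import SsAlignment, ss_to_segments

__all__ = [
    "SignalPointMapping",
    "F1Result",
    "mapping_from_ss",
    "f1_score",
    "model_correlation",
    "pool_f1",
    "depth_sweep",
]

UNMAPPED = -1


@dataclass
class SignalPointMapping:
    """Per-sample base assignment; ``UNMAPPED`` (-1) marks unassigned points."""

    base_index: np.ndarray  # int array, one entry per signal sample
    ref_length: int

    def __post_init__(self) -> None:
        self.base_index = np.asarray(self.base_index, dtype=np.int64)

    @property
    def n_points(self) -> int:
        return int(self.base_index.size)


@dataclass
class F1Result:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def mapping_from_ss(
    aln: SsAlignment, signal_len: int, ref_length: int | None = None
) -> SignalPointMapping:
    """Expand an ss alignment into a per-sample base map.

    Matched samples map to their base; inserted samples, and samples
    outside the alignment span, stay unmapped.
    """
    if ref_length is None:
        ref_length = aln.seq_start + aln.n_bases
    base = np.full(signal_len, UNMAPPED, dtype=np.int64)
    for b, (s, e) in ss_to_segments(aln, signal_len, ref_length):
        base[s:e] = b
    return SignalPointMapping(base_index=base, ref_length=ref_length)


def f1_score(
    query: SignalPointMapping, truth: SignalPointMapping, tolerance: int = 1
) -> F1Result:
    """Classify every signal point of ``query`` against ``truth``.

    The tolerance applies only where both mappings assign a base.  Raises
    ``ValueError`` on signal-length mismatch.
    """
    if query.n_points != truth.n_points:
        raise ValueError(
            f"signal length mismatch: query {query.n_points}, truth {truth.n_points}"
        )
    q, t = query.base_index, truth.base_index
    q_mapped = q != UNMAPPED
    t_mapped = t != UNMAPPED
    both = q_mapped & t_mapped
    close = both & (np.abs(q - t) <= tolerance)
    tp = int(close.sum())
    fp = int((q_mapped & ~t_mapped).sum() + (both & ~close).sum())
    fn = int((t_mapped & ~q_mapped).sum())
    tn = int((~q_mapped & ~t_mapped).sum())
    return F1Result(tp=tp, fp=fp, fn=fn, tn=tn)


def pool_f1(results: list[F1Result]) -> F1Result:
    """Micro-average: sum the per-read confusion counts, then score."""
    return F1Result(
        tp=sum(r.tp for r in results),
        fp=sum(r.fp for r in results),
        fn=sum(r.fn for r in results),
        tn=sum(r.tn for r in results),
    )


def model_correlation(a: KmerModel, b: KmerModel) -> tuple[float, int]:
    """Pearson correlation of level means over shared k-mers.

    Both models must have the same k (collapse the larger one first).
    Returns ``(r, n_shared)``; fewer than 3 shared k-mers is an error.
    """
    if a.k != b.k:
        raise ValueError(
            f"models have different k ({a.k} vs {b.k}); collapse to a common "
            "register first"
        )
    shared = sorted(set(a.levels) & set(b.levels))
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared k-mers; need at least 3")
    xa = np.array([a.levels[kmer][0] for kmer in shared])
    xb = np.array([b.levels[kmer][0] for kmer in shared])
    r, _ = stats.pearsonr(xa, xb)
    return float(r), len(shared)


def depth_sweep(
    truth_model: KmerModel,
    depths: list[int],
    read_length: int = 500,
    seed: int = 1,
    rna_mode: bool = False,
):
    """Rebuild the model at increasing per-k-mer sampling depths.

    For each target depth, simulates just enough de Bruijn-covering reads
    for every k-mer to reach that many stored events, rebuilds the model,
    and correlates it with the truth.  Returns a DataFrame with columns
    ``depth, n_reads, pearson, n_shared, min_stored, median_stored`` —
    the synthetic analogue of an input-size titration, which saturates
    once every k-mer has been seen ~100 times.
    """
    import numpy as _np
    import pandas as pd

    from .estimators import PoreModelBuilder
    from .simulate import SimConfig, reads_for_target_depth, simulate_dataset

    rows = []
    for i, depth in enumerate(depths):
        n_reads = reads_for_target_depth(depth, truth_model.k, read_length)
        cfg = SimConfig(
            truth_model=truth_model,
            n_reads=n_reads,
            read_length=read_length,
            rna_mode=rna_mode,
            seed=seed + i,
        )
        ds = simulate_dataset(cfg)
        builder = PoreModelBuilder(
            k=truth_model.k, sample_limit=depth, rna=rna_mode
        )
        builder.fit_from_dataset(ds)
        stored = [len(v) for v in builder.accumulator_.samples.values()]
        r, n_shared = model_correlation(builder.model_, truth_model)
        rows.append(
            {
                "depth": depth,
                "n_reads": n_reads,
                "pearson": r,
                "n_shared": n_shared,
                "min_stored": int(min(stored)),
                "median_stored": float(_np.median(stored)),
            }
        )
    return pd.DataFrame(rows)
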