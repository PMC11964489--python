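"""Significant base positions within a k-mer, and model collapsing.

All k bases in the pore influence the current, but unevenly.  For each base
index we partition the model's levels into four per-base collections (the
positional "1-mer model": for a complete model each base holds 4**(k-1)
levels), histogram every ordered pair of collections on shared bins, and
Pearson-correlate the count vectors.  An index whose mean pairwise
similarity falls below a threshold (default 0.96) discriminates the four
bases and is called significant.  A large model can then be collapsed onto
a contiguous set of kept indices by group-averaging, giving a lightweight
model with 4**(k-k') times fewer rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import stats

from .errors import FormatError
from .model_io import ALPHABET, KmerModel

__all__ = [
    "PositionalBaseModel",
    "SignificanceReport",
    "build_positional_models",
    "histogram_similarity",
    "significant_indices",
    "collapse_model",
    "density_profile",
    "model_size_ratio",
]


@dataclass
class PositionalBaseModel:
    """Levels of all k-mers grouped by the base at one index."""

    base_index: int
    levels: dict[str, np.ndarray]  # base -> level array


@dataclass
class SignificanceReport:
    mean_similarities: list[float]  # one per base index
    significant_indices: list[int]  # ascending
    threshold: float
    num_bins: int


def build_positional_models(model: KmerModel) -> list[PositionalBaseModel]:
    """Partition the model's levels by the base at each of the k indices."""
    per_index: list[dict[str, list[float]]] = [
        {b: [] for b in ALPHABET} for _ in range(model.k)
    ]
    for kmer, (mean, _) in model.levels.items():
        for i, base in enumerate(kmer):
            if base not in ALPHABET:
                raise FormatError(f"k-mer {kmer!r} has base {base!r} outside ACGT")
            per_index[i][base].append(mean)
    return [
        PositionalBaseModel(
            base_index=i,
            levels={b: np.array(v, dtype=np.float64) for b, v in groups.items()},
        )
        for i, groups in enumerate(per_index)
    ]


def histogram_similarity(
    x: np.ndarray,
    y: np.ndarray,
    num_bins: int = 10,
    bins_as_edges: bool = True,
) -> float:
    """Pearson correlation of two level histograms on shared bins.

    Bin edges are ``num_bins`` evenly spaced numbers spanning the pooled
    range of both lists (so ``num_bins - 1`` bins); with
    ``bins_as_edges=False`` the pooled range is instead divided into
    ``num_bins`` bins.  If either count vector has zero variance the shapes
    are degenerate and the similarity is defined as 1 (with a warning).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("level lists must be non-empty")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    if hi == lo:
        hi = lo + 1e-9
    edges = (
        np.linspace(lo, hi, num_bins)
        if bins_as_edges
        else np.linspace(lo, hi, num_bins + 1)
    )
    hx, _ = np.histogram(x, bins=edges)
    hy, _ = np.histogram(y, bins=edges)
    if np.ptp(hx) == 0 or np.ptp(hy) == 0:
        warnings.warn("degenerate histogram (zero count variance); similarity := 1")
        return 1.0
    if np.array_equal(hx, hy):  # avoid float drift on identical shapes
        return 1.0
    r, _ = stats.pearsonr(hx, hy)
    return float(r)


def significant_indices(
    model: KmerModel,
    num_bins: int = 10,
    threshold: float = 0.96,
    bins_as_edges: bool = True,
) -> SignificanceReport:
    """Mean pairwise histogram similarity per index; below-threshold indices.

    All 12 ordered base pairs are compared per index (symmetric duplicates
    do not change the mean).  Incomplete models are processed on the k-mers
    available, with a warning.
    """
    if model.completeness() < 1.0:
        warnings.warn(
            f"model covers {model.completeness():.1%} of k-mer space; "
            "significance computed on available k-mers"
        )
    positional = build_positional_models(model)
    mean_sims: list[float] = []
    for pm in positional:
        sims = [
            histogram_similarity(
                pm.levels[bi], pm.levels[bj], num_bins, bins_as_edges
            )
            for bi in ALPHABET
            for bj in ALPHABET
            if bj != bi
        ]
        mean_sims.append(float(np.mean(sims)))
    sig = [i for i, s in enumerate(mean_sims) if s < threshold]
    return SignificanceReport(
        mean_similarities=mean_sims,
        significant_indices=sig,
        threshold=threshold,
        num_bins=num_bins,
    )


def collapse_model(model: KmerModel, keep_indices: list[int]) -> KmerModel:
    """Collapse onto a contiguous index set by group-averaging levels.

    Each reduced k-mer's level is the mean over all parents sharing that
    subsequence at ``keep_indices`` (4**(k-k') parents per child for a
    complete model).  Spreads, when present, are averaged the same way.
    Non-contiguous index sets are refused: the reduced model's register
    within the pore would be ambiguous.
    """
    keep = sorted(keep_indices)
    if not keep:
        raise ValueError("keep_indices is empty")
    if keep[0] < 0 or keep[-1] >= model.k:
        raise ValueError(f"keep_indices out of range for k={model.k}")
    if keep != list(range(keep[0], keep[-1] + 1)):
        raise ValueError("keep_indices must be contiguous")
    lo, hi = keep[0], keep[-1] + 1
    groups: dict[str, list[tuple[float, float | None]]] = {}
    for kmer, pair in model.levels.items():
        groups.setdefault(kmer[lo:hi], []).append(pair)
    with_sd = model.has_stddev
    levels: dict[str, tuple[float, float | None]] = {}
    for child, pairs in groups.items():
        mu = float(np.mean([m for m, _ in pairs]))
        sd = (
            float(np.mean([0.0 if s is None else s for _, s in pairs]))
            if with_sd
            else None
        )
        levels[child] = (mu, sd)
    return KmerModel(k=hi - lo, levels=levels, space=model.space)


def expand_model(model: KmerModel, k_target: int, position: int = 0) -> KmerModel:
    """Replicate each level across all parents containing it at ``position``.

    Inverse-direction helper for collapse consistency checks: collapsing an
    expanded model back onto the original window recovers it exactly.
    """
    pad = k_target - model.k
    if pad < 0 or position < 0 or position > pad:
        raise ValueError("target k must fit the source model at the given position")
    levels: dict[str, tuple[float, float | None]] = {}
    for kmer, pair in model.levels.items():
        for left in product(ALPHABET, repeat=position):
            for right in product(ALPHABET, repeat=pad - position):
                levels["".join(left) + kmer + "".join(right)] = pair
    return KmerModel(k=k_target, levels=levels, space=model.space)


def density_profile(model: KmerModel):
    """Long-form table (base_index, base, level) for density plotting."""
    import pandas as pd

    rows = []
    for pm in build_positional_models(model):
        for base, levels in pm.levels.items():
            for level in levels:
                rows.append((pm.base_index, base, float(level)))
    return pd.DataFrame(rows, columns=["base_index", "base", "level"])


def model_size_ratio(k_large: int, k_small: int, alphabet_size: int = 4) -> int:
    """How many times more k-mers the larger model holds: |A|**(kL - kS)."""
    if k_large < k_small:
        raise ValueError("k_large must be >= k_small")
    return alphabet_size ** (k_large - k_small)
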