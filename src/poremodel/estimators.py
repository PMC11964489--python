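"""Scikit-learn-style estimators wrapping the model-building pipeline.

:class:`PoreModelBuilder` is the end-to-end fit: given ``(ReadRecord,
SsAlignment)`` pairs it estimates global signal statistics, Med-MAD
normalizes each read, samples and filters per-k-mer events, and summarizes
them into a k-mer model in both normalized and pA spaces.

:class:`SignificantBaseFinder` fits on a :class:`KmerModel` and exposes the
per-index similarity profile; its ``transform`` collapses a model onto the
contiguous span of significant indices.

Both follow the sklearn protocol (``get_params``/``set_params``, fitted
attributes with trailing underscores) and compose with ``clone`` and
pipelines.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .build import (
    ScalingParams,
    estimate_globals,
    make_scaler,
    rescale_stddev,
    summarize,
    to_pa,
)
from .errors import DegenerateSignalError, EmptyResultError
from .events import (
    KmerAccumulator,
    SamplingConfig,
    accumulate,
    events_for_read,
    mask_indel_neighborhood,
)
from .model_io import KmerModel
from .signals import ReadRecord
from .ss import SsAlignment

__all__ = ["PoreModelBuilder", "SignificantBaseFinder"]

logger = logging.getLogger(__name__)


class PoreModelBuilder(BaseEstimator):
    """Build a de novo k-mer model from signal-to-sequence alignments.

    Parameters
    ----------
    k : k-mer length of the model.
    sample_limit : cap of stored events per k-mer.
    min_dur, max_dur : dwell-time filter bounds in samples (strict by
        default; ``inclusive_duration`` switches to closed bounds).
    max_event_stddev : within-event spread filter in normalized units,
        disabled when ``None``.
    move_offset : whole-base shift between events and k-mer windows.
    indel_skip : bases masked around insertions/deletions.
    rna : traverse reads 3'->5' to match direct-RNA signal order.
    scaling : per-read normalization, ``"med-mad"`` or ``"none"``.
    stat : per-k-mer level statistic, ``"mean"`` or ``"median"``.
    spread : ``"mean_of_stddevs"`` (average within-event spread) or
        ``"stddev_of_means"``.
    stddev_interval : heuristic (lo, hi) the spread column is rescaled to,
        or ``None`` to keep raw spreads.
    min_samples : minimum stored events for a k-mer to enter the model.
    strict_cap : count every observation against the cap, stored or not.

    Attributes (after ``fit``)
    --------------------------
    model_ : KmerModel in normalized space.
    model_pa_ : KmerModel transformed to picoamperes.
    globals_ : ScalingParams estimated from the fitted reads.
    accumulator_ : the underlying KmerAccumulator.
    completeness_ : dict of k-mer-space coverage fractions.
    n_reads_, n_reads_skipped_ : read accounting.
    """

    def __init__(
        self,
        k: int = 5,
        sample_limit: int = 5000,
        min_dur: int = 20,
        max_dur: int = 40,
        max_event_stddev: float | None = None,
        move_offset: int = 0,
        indel_skip: int = 2,
        rna: bool = False,
        scaling: str = "med-mad",
        stat: str = "mean",
        spread: str = "mean_of_stddevs",
        stddev_interval: tuple[float, float] | None = (2.5, 4.0),
        min_samples: int = 1,
        inclusive_duration: bool = False,
        strict_cap: bool = False,
    ):
        self.k = k
        self.sample_limit = sample_limit
        self.min_dur = min_dur
        self.max_dur = max_dur
        self.max_event_stddev = max_event_stddev
        self.move_offset = move_offset
        self.indel_skip = indel_skip
        self.rna = rna
        self.scaling = scaling
        self.stat = stat
        self.spread = spread
        self.stddev_interval = stddev_interval
        self.min_samples = min_samples
        self.inclusive_duration = inclusive_duration
        self.strict_cap = strict_cap

    def _sampling_config(self) -> SamplingConfig:
        return SamplingConfig(
            k=self.k,
            num_samples=self.sample_limit,
            move_offset=self.move_offset,
            min_dur=self.min_dur,
            max_dur=self.max_dur,
            max_event_stddev=self.max_event_stddev,
            indel_skip=self.indel_skip,
            rna_mode=self.rna,
            inclusive_duration=self.inclusive_duration,
            strict_cap=self.strict_cap,
        )

    def fit(
        self,
        X: Iterable[tuple[ReadRecord, SsAlignment]],
        y: None = None,
    ) -> "PoreModelBuilder":
        """Sample events from aligned reads and summarize the model."""
        pairs = list(X)
        if not pairs:
            raise EmptyResultError("no (read, alignment) pairs to fit on")
        cfg = self._sampling_config()
        scaler = make_scaler(self.scaling)
        self.globals_ = (
            estimate_globals(rec for rec, _ in pairs)
            if self.scaling == "med-mad"
            else ScalingParams(method="none", global_mean=0.0, global_stddev=1.0)
        )
        acc = KmerAccumulator(cfg=cfg)
        n_skipped = 0
        for rec, aln in pairs:
            if rec.sequence is None or len(rec.sequence) < cfg.k:
                n_skipped += 1
                continue
            excluded = (
                mask_indel_neighborhood(aln, cfg.indel_skip)
                if cfg.indel_skip >= 0
                else set()
            )
            try:
                for kmer, ev in events_for_read(rec, aln, cfg, scaler, excluded):
                    acc.add(kmer, ev)
            except DegenerateSignalError:
                n_skipped += 1
                continue
        if not acc.samples:
            raise EmptyResultError("zero events stored; nothing to summarize")
        model = summarize(
            acc, stat=self.stat, spread=self.spread, min_samples=self.min_samples
        )
        if self.stddev_interval is not None and model.has_stddev:
            model = rescale_stddev(model, *self.stddev_interval)
        self.accumulator_ = acc
        self.model_ = model
        self.model_pa_ = to_pa(model, self.globals_)
        self.completeness_ = acc.completeness_report()
        self.n_reads_ = len(pairs) - n_skipped
        self.n_reads_skipped_ = n_skipped
        logger.info(
            "fitted model on %d reads (%d skipped); %d k-mers, %.1f%% complete",
            self.n_reads_,
            n_skipped,
            len(model),
            100 * model.completeness(),
        )
        return self

    def fit_from_dataset(self, dataset) -> "PoreModelBuilder":
        """Fit from a :class:`poremodel.simulate.SimulatedDataset`."""
        return self.fit(
            (rec, dataset.alignments[rec.read_id]) for rec in dataset.records
        )


class SignificantBaseFinder(BaseEstimator, TransformerMixin):
    """Locate the base positions within a k-mer that drive the current.

    Attributes (after ``fit``)
    --------------------------
    mean_similarities_ : per-index mean pairwise histogram similarity.
    significant_indices_ : indices below the threshold, ascending.
    report_ : the full SignificanceReport.
    """

    def __init__(
        self,
        num_bins: int = 10,
        threshold: float = 0.96,
        bins_as_edges: bool = True,
    ):
        self.num_bins = num_bins
        self.threshold = threshold
        self.bins_as_edges = bins_as_edges

    def fit(self, X: KmerModel, y: None = None) -> "SignificantBaseFinder":
        from .significance import significant_indices

        report = significant_indices(
            X,
            num_bins=self.num_bins,
            threshold=self.threshold,
            bins_as_edges=self.bins_as_edges,
        )
        self.report_ = report
        self.mean_similarities_ = report.mean_similarities
        self.significant_indices_ = report.significant_indices
        return self

    def transform(self, X: KmerModel) -> KmerModel:
        """Collapse ``X`` onto the contiguous span of significant indices."""
        from .significance import collapse_model

        check_is_fitted(self, "significant_indices_")
        sig = self.significant_indices_
        if not sig:
            raise EmptyResultError("no significant indices; nothing to collapse")
        keep = list(range(min(sig), max(sig) + 1))
        return collapse_model(X, keep)

    def fit_transform(self, X: KmerModel, y: None = None, **kwargs) -> KmerModel:
        return self.fit(X).transform(X)
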