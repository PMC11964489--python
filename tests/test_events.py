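"""Event sampling: window pairing, filters, indel masking, accumulation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import poremodel as pm
from poremodel.events import EventSample, KmerAccumulator, SamplingConfig
from poremodel.ss import OpKind, SsOp

from conftest import make_read, uniform_alignment

identity = lambda x: np.asarray(x, dtype=float)  # noqa: E731


def sliding_windows(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


class TestEventsForRead:
    def test_perfect_read_counts(self):
        seq = "ACGTACGTACGTACGTACGT"
        rec = make_read(seq)
        aln = uniform_alignment(len(seq))
        cfg = SamplingConfig(k=5)
        events = list(pm.events_for_read(rec, aln, cfg, identity))
        assert len(events) == len(seq) - 5 + 1
        assert all(ev.duration == 30 for _, ev in events)
        assert [km for km, _ in events] == sliding_windows(seq, 5)

    def test_move_offset_shifts_labels(self):
        seq = "ACGTACGTACGTACGTACGT"
        rec = make_read(seq)
        aln = uniform_alignment(len(seq))
        cfg = SamplingConfig(k=5, move_offset=2)
        events = list(pm.events_for_read(rec, aln, cfg, identity))
        windows = sliding_windows(seq, 5)
        # event of base i+2 carries the label of window i
        assert [km for km, _ in events] == windows[: len(seq) - 5 + 1]
        # and those events are the segments of bases 2..(n-k+2)
        segs = pm.ss_to_segments(aln, rec.raw.size, len(seq))
        assert len(events) == len(
            [b for b, _ in segs if 2 <= b < 2 + len(windows)]
        )

    def test_read_shorter_than_k(self):
        rec = make_read("ACG")
        aln = uniform_alignment(3)
        assert list(pm.events_for_read(rec, aln, SamplingConfig(k=5), identity)) == []

    def test_event_statistics_match_numpy_on_slices(self):
        rng = np.random.default_rng(0)
        seq = "ACGTAC"
        dwell = [25, 30, 35, 22, 28, 33]
        raw = rng.integers(0, 500, size=sum(dwell))
        rec = pm.ReadRecord("r", raw, 2048, 2048, 0, 4000, sequence=seq)
        aln = pm.SsAlignment(ops=[SsOp(OpKind.MATCH, d) for d in dwell])
        cfg = SamplingConfig(k=3)
        events = list(pm.events_for_read(rec, aln, cfg, identity))
        pa = rec.to_pa()
        bounds = np.concatenate([[0], np.cumsum(dwell)])
        for i, (km, ev) in enumerate(events):
            seg = pa[bounds[i] : bounds[i + 1]]
            assert ev.mean == pytest.approx(seg.mean(), rel=1e-9)
            assert ev.stddev == pytest.approx(seg.std(), rel=1e-6, abs=1e-9)
            assert ev.duration == dwell[i]

    def test_rna_mode_reverses_traversal_not_kmers(self):
        seq = "AACCGGTTAC"
        rec = make_read(seq)
        aln = uniform_alignment(len(seq))
        fw = list(pm.events_for_read(rec, aln, SamplingConfig(k=3), identity))
        rv = list(
            pm.events_for_read(rec, aln, SamplingConfig(k=3, rna_mode=True), identity)
        )
        assert len(fw) == len(rv)
        # same event statistics (signal is untouched), relabelled only
        assert [e for _, e in fw] == [e for _, e in rv]
        # labels are the 5'->3' windows taken in reverse traversal order
        windows = sliding_windows(seq, 3)
        assert [km for km, _ in rv] == windows[::-1]


class TestFilters:
    def test_strict_bounds(self):
        cfg = SamplingConfig(min_dur=20, max_dur=40)
        assert not pm.passes_filters(EventSample(0, 0, 20), cfg)
        assert not pm.passes_filters(EventSample(0, 0, 40), cfg)
        assert pm.passes_filters(EventSample(0, 0, 30), cfg)

    def test_duration_sweep_exhaustive(self):
        cfg = SamplingConfig(min_dur=20, max_dur=40)
        accepted = {
            d for d in range(1, 61) if pm.passes_filters(EventSample(0, 0, d), cfg)
        }
        assert accepted == set(range(21, 40))

    def test_inclusive_variant(self):
        cfg = SamplingConfig(min_dur=20, max_dur=40, inclusive_duration=True)
        accepted = {
            d for d in range(1, 61) if pm.passes_filters(EventSample(0, 0, d), cfg)
        }
        assert accepted == set(range(20, 41))

    def test_stddev_filter(self):
        cfg = SamplingConfig(max_event_stddev=1.5)
        assert pm.passes_filters(EventSample(0, 1.5, 30), cfg)
        assert not pm.passes_filters(EventSample(0, 1.6, 30), cfg)


def brute_force_mask(aln, skip):
    """Distance-to-indel oracle over the expanded op walk."""
    deleted, boundaries = [], []
    base = aln.seq_start
    for op in aln.ops:
        if op.kind is OpKind.MATCH:
            base += 1
        elif op.kind is OpKind.DELETION:
            deleted.extend(range(base, base + op.length))
            base += op.length
        else:
            boundaries.append(base)
    out = set()
    last = base
    for b in range(aln.seq_start, last + skip + 1):
        if any(abs(b - d) <= skip for d in deleted):
            out.add(b)
        if skip > 0 and any(bd - skip <= b < bd + skip for bd in boundaries):
            out.add(b)
    return out


class TestIndelMask:
    def test_deletion_window(self):
        ops = [SsOp(OpKind.MATCH, 30)] * 5 + [SsOp(OpKind.DELETION, 2)] + [
            SsOp(OpKind.MATCH, 30)
        ] * 5
        aln = pm.SsAlignment(ops=ops)
        assert pm.mask_indel_neighborhood(aln, 2) == {3, 4, 5, 6, 7, 8}
        assert pm.mask_indel_neighborhood(aln, 0) == {5, 6}

    @given(
        st.lists(
            st.tuples(
                st.sampled_from([OpKind.MATCH, OpKind.DELETION, OpKind.INSERTION]),
                st.integers(1, 4),
            ).map(lambda t: SsOp(*t)),
            min_size=1,
            max_size=20,
        ),
        st.integers(0, 3),
    )
    def test_oracle_equivalence(self, ops, skip):
        aln = pm.SsAlignment(ops=ops)
        assert pm.mask_indel_neighborhood(aln, skip) == brute_force_mask(aln, skip)

    def test_masked_windows_dropped(self):
        seq = "ACGTACGTAC"
        rec = make_read(seq)
        ops = [SsOp(OpKind.MATCH, 30)] * 4 + [SsOp(OpKind.DELETION, 1)] + [
            SsOp(OpKind.MATCH, 30)
        ] * 5
        aln = pm.SsAlignment(ops=ops)
        cfg = SamplingConfig(k=3, indel_skip=0)
        excluded = pm.mask_indel_neighborhood(aln, 0)
        kept = [
            km
            for km, _ in pm.events_for_read(rec, aln, cfg, identity, excluded)
        ]
        # base 4 is deleted; windows 2,3,4 overlap it and are dropped,
        # leaving the events of bases 0,1 (windows 0,1) and 5,6,7
        assert kept == [seq[w : w + 3] for w in (0, 1, 5, 6, 7)]


class TestAccumulate:
    def _stream(self, kmer, n, duration=30):
        return ((kmer, EventSample(1.0, 0.1, duration)) for _ in range(n))

    def test_cap_limits_storage(self):
        cfg = SamplingConfig(k=5, num_samples=5000)
        acc = pm.accumulate(self._stream("ACGTA", 6000), cfg)
        assert acc.n_stored("ACGTA") == 5000
        assert acc.counters["ACGTA"] == 6000

    def test_empty_stream(self):
        cfg = SamplingConfig(k=5)
        acc = pm.accumulate(iter(()), cfg)
        assert acc.samples == {}
        assert acc.completeness_report()["frac_ge_1"] == 0.0

    def test_interleaved_tallies(self, rng):
        cfg = SamplingConfig(k=1, num_samples=30)
        kmers = rng.choice(["A", "C"], size=200)
        acc = pm.accumulate(
            ((km, EventSample(0.0, 0.0, 25)) for km in kmers), cfg
        )
        counts = {"A": int((kmers == "A").sum()), "C": int((kmers == "C").sum())}
        assert acc.counters == counts
        assert {k: acc.n_stored(k) for k in counts} == {
            k: min(v, 30) for k, v in counts.items()
        }

    def test_strict_cap_counts_observations(self):
        # filtered-out observations still consume the strict cap
        cfg = SamplingConfig(k=1, num_samples=5, strict_cap=True)
        stream = [("A", EventSample(0.0, 0.0, 10))] * 3 + [
            ("A", EventSample(0.0, 0.0, 30))
        ] * 5
        acc = pm.accumulate(iter(stream), cfg)
        assert acc.n_stored("A") == 2  # only slots 4,5 both pass and fit
        cfg2 = SamplingConfig(k=1, num_samples=5, strict_cap=False)
        acc2 = pm.accumulate(iter(stream), cfg2)
        assert acc2.n_stored("A") == 5

    def test_stored_events_respect_filters(self, small_dataset):
        cfg = SamplingConfig(k=3, num_samples=50)
        ds = small_dataset
        acc = KmerAccumulator(cfg=cfg)
        for rec in ds.records:
            for km, ev in pm.events_for_read(
                rec, ds.alignments[rec.read_id], cfg, identity
            ):
                acc.add(km, ev)
        for events in acc.samples.values():
            assert all(pm.passes_filters(ev, cfg) for ev in events)
        total = sum(len(v) for v in acc.samples.values())
        assert total <= 4**cfg.k * cfg.num_samples
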