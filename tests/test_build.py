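"""Normalization, per-k-mer summaries, pA transform, spread rescaling."""

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats

import poremodel as pm
from poremodel.build import make_scaler
from poremodel.errors import DegenerateSignalError, EmptyResultError
from poremodel.events import EventSample, KmerAccumulator, SamplingConfig

finite_arrays = st.lists(
    st.floats(-1e4, 1e4, allow_nan=False), min_size=3, max_size=50
).map(np.array)


class TestMedMad:
    def test_hand_arithmetic(self):
        out = pm.med_mad_normalize(np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    @given(finite_arrays)
    def test_self_normalization(self, x):
        assume(np.median(np.abs(x - np.median(x))) > 1e-6)
        out = pm.med_mad_normalize(x)
        assert np.median(out) == pytest.approx(0.0, abs=1e-9)
        assert np.median(np.abs(out)) == pytest.approx(1.0, rel=1e-9)

    @given(finite_arrays, st.floats(0.1, 100), st.floats(-1e3, 1e3))
    def test_affine_invariance(self, x, a, b):
        assume(np.median(np.abs(x - np.median(x))) > 1e-6)
        out1 = pm.med_mad_normalize(x)
        out2 = pm.med_mad_normalize(a * x + b)
        np.testing.assert_allclose(out1, out2, rtol=1e-6, atol=1e-8)

    def test_degenerate(self):
        with pytest.raises(DegenerateSignalError):
            pm.med_mad_normalize(np.array([5.0, 5.0, 5.0, 5.0]))
        with pytest.raises(DegenerateSignalError):
            pm.med_mad_normalize(np.array([1.0]))

    def test_consistency_factor(self):
        x = np.array([1.0, 2.0, 3.0])
        out = pm.med_mad_normalize(x, consistency_factor=True)
        np.testing.assert_allclose(out, np.array([-1.0, 0.0, 1.0]) / 1.4826)

    def test_unknown_scaler(self):
        with pytest.raises(ValueError):
            make_scaler("zscore")


def acc_with(samples: dict[str, list[EventSample]], k=1) -> KmerAccumulator:
    acc = KmerAccumulator(cfg=SamplingConfig(k=k, num_samples=10**6))
    for km, evs in samples.items():
        for ev in evs:
            acc.samples.setdefault(km, []).append(ev)
            acc.counters[km] = acc.counters.get(km, 0) + 1
    return acc


class TestSummarize:
    def test_mean_of_two(self):
        acc = acc_with({"A": [EventSample(0.9, 0.1, 30), EventSample(1.1, 0.3, 30)]})
        model = pm.summarize(acc)
        mu, sd = model.levels["A"]
        assert mu == pytest.approx(1.0)
        assert sd == pytest.approx(0.2)  # mean of within-event spreads

    def test_median_variant(self, rng):
        vals = rng.lognormal(0, 1, size=31)
        acc = acc_with({"A": [EventSample(v, 0.0, 30) for v in vals]})
        model = pm.summarize(acc, stat="median")
        assert model.levels["A"][0] == pytest.approx(np.median(vals))

    def test_spread_of_means_variant(self, rng):
        vals = rng.normal(0, 1, size=40)
        acc = acc_with({"A": [EventSample(v, 9.9, 30) for v in vals]})
        model = pm.summarize(acc, spread="stddev_of_means")
        assert model.levels["A"][1] == pytest.approx(np.std(vals))

    def test_min_samples_omits_sparse_kmers(self):
        acc = acc_with(
            {"A": [EventSample(1, 0, 30)] * 5, "C": [EventSample(2, 0, 30)]}
        )
        model = pm.summarize(acc, min_samples=3)
        assert set(model.levels) == {"A"}

    def test_empty(self):
        with pytest.raises(EmptyResultError):
            pm.summarize(acc_with({}))


class TestPaTransform:
    def test_zero_maps_to_global_mean(self):
        m = pm.KmerModel(1, {"A": (0.0, None)}, space="normalized")
        params = pm.ScalingParams(global_mean=100.0, global_stddev=20.0)
        assert pm.to_pa(m, params).levels["A"][0] == pytest.approx(100.0)

    def test_printed_formula(self):
        m = pm.KmerModel(1, {"A": (1.0, None)}, space="normalized")
        params = pm.ScalingParams(global_mean=100.0, global_stddev=20.0)
        out = pm.to_pa(m, params)
        assert out.levels["A"][0] == pytest.approx(120.0)
        assert out.space == "pA"

    def test_invertible(self, truth_3mer):
        params = pm.ScalingParams(global_mean=87.3, global_stddev=16.2)
        out = pm.to_pa(truth_3mer, params)
        for km, (mu, _) in out.levels.items():
            back = (mu - params.global_mean) / params.global_stddev
            assert back == pytest.approx(truth_3mer.levels[km][0], rel=1e-12)

    def test_requires_normalized_space(self, truth_3mer):
        params = pm.ScalingParams(global_mean=0, global_stddev=1)
        pa = pm.to_pa(truth_3mer, params)
        with pytest.raises(ValueError):
            pm.to_pa(pa, params)


class TestRescaleStddev:
    def test_extremes_hit_interval(self, truth_3mer):
        out = pm.rescale_stddev(truth_3mer)
        sds = [sd for _, sd in out.levels.values()]
        assert min(sds) == pytest.approx(2.5)
        assert max(sds) == pytest.approx(4.0)

    def test_all_equal_maps_to_midpoint(self):
        m = pm.KmerModel(1, {b: (0.0, 0.7) for b in "ACGT"}, space="normalized")
        out = pm.rescale_stddev(m)
        assert all(sd == pytest.approx(3.25) for _, sd in out.levels.values())

    def test_monotone(self, truth_3mer):
        out = pm.rescale_stddev(truth_3mer)
        before = [truth_3mer.levels[km][1] for km in sorted(truth_3mer.levels)]
        after = [out.levels[km][1] for km in sorted(out.levels)]
        rho, _ = stats.spearmanr(before, after)
        assert rho == pytest.approx(1.0)


class TestGlobals:
    def test_pooled_brute_force(self):
        r1 = pm.ReadRecord("a", np.array([0, 100, 200]), 2048, 2048, 0, 4000)
        r2 = pm.ReadRecord("b", np.array([50, 150]), 2048, 1024, 10, 4000)
        params = pm.estimate_globals([r1, r2])
        pooled = np.concatenate([r1.to_pa(), r2.to_pa()])
        assert params.global_mean == pytest.approx(pooled.mean())
        assert params.global_stddev == pytest.approx(pooled.std())

    def test_constant_signal_gives_zero_stddev(self):
        r = pm.ReadRecord("a", np.full(10, 7), 2048, 2048, 0, 4000)
        params = pm.estimate_globals([r])
        assert params.global_stddev == pytest.approx(0.0)
        m = pm.KmerModel(1, {"A": (0.0, None)}, space="normalized")
        with pytest.raises(ValueError):
            pm.to_pa(m, params)

    def test_empty(self):
        with pytest.raises(EmptyResultError):
            pm.estimate_globals([])

    def test_subsample_stability(self, small_dataset):
        full = pm.estimate_globals(small_dataset.records)
        half = pm.estimate_globals(small_dataset.records[::2])
        assert half.global_mean == pytest.approx(full.global_mean, rel=0.05)
        assert half.global_stddev == pytest.approx(full.global_stddev, rel=0.05)
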