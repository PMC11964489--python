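import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poremodel as pm

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def truth_3mer() -> pm.KmerModel:
    return pm.random_truth_model(3, seed=2)


@pytest.fixture(scope="session")
def truth_5mer() -> pm.KmerModel:
    return pm.random_truth_model(5, seed=11)


@pytest.fixture(scope="session")
def small_dataset(truth_3mer) -> pm.SimulatedDataset:
    """~25 short reads covering every 3-mer ~20 times; fast to rebuild."""
    from poremodel.simulate import reads_for_target_depth

    n = reads_for_target_depth(20, 3, 200)
    cfg = pm.SimConfig(
        truth_model=truth_3mer, n_reads=n, read_length=200, de_bruijn=True, seed=3
    )
    return pm.simulate_dataset(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_read(seq: str, dwell: int = 30, level: float = 100.0) -> pm.ReadRecord:
    """Constant-level read with one fixed-dwell segment per base."""
    raw = np.full(len(seq) * dwell, level, dtype=np.int32)
    return pm.ReadRecord(
        read_id="r0",
        raw=raw,
        digitisation=2048,
        range_pA=2048,
        offset=0,
        sampling_rate=4000,
        sequence=seq,
    )


def uniform_alignment(n_bases: int, dwell: int = 30) -> pm.SsAlignment:
    return pm.SsAlignment(
        ops=[pm.SsOp(pm.OpKind.MATCH, dwell) for _ in range(n_bases)]
    )
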