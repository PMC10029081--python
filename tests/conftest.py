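import numpy as np
import pytest

from halosynth import (HALO, BucketSpec, PatientRecord, Visit,
                       build_vocabulary, simulate)
from halosynth.network import HALOConfig, HALONetwork


@pytest.fixture
def tiny_vocab():
    """8 medical codes + 2 labels + specials: 12 positions total."""
    return build_vocabulary(
        [f"M{i}" for i in range(8)], ["L0", "L1"], order_seed=3,
    )


@pytest.fixture
def tiny_config():
    return HALOConfig(M=1, N=2, n_emb=8, n_heads=2, max_T=4, dropout=0.0)


@pytest.fixture
def tiny_net(tiny_vocab, tiny_config):
    return HALONetwork(tiny_config, len(tiny_vocab),
                       rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_process():
    return simulate.make_process("small", seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_process):
    return simulate.sample_cohort_sim(small_process, 200, seed=8)


@pytest.fixture(scope="session")
def mini_results(small_process, small_cohort):
    """A briefly trained small model, for sampling/evaluation tests that
    need plausible (not converged) parameters."""
    model = HALO(small_cohort, small_process.vocabulary(),
                 small_process.bucket_specs(),
                 M=1, N=2, n_emb=32, n_heads=4, max_T=12, dropout=0.0)
    return model.fit(epochs=2, seed=0)


@pytest.fixture(scope="session")
def train_cohort_2k(small_process):
    return simulate.sample_cohort_sim(small_process, 2000, seed=8)


@pytest.fixture(scope="session")
def trained_results(small_process, train_cohort_2k):
    """The reduced-scale reference fit used by the acceptance checks:
    2 visit-level blocks, 2 masked layers, 64-dim embeddings, trained with
    the standard recipe (Adam 1e-4, batch 48, 50 epochs)."""
    model = HALO(train_cohort_2k, small_process.vocabulary(),
                 small_process.bucket_specs(),
                 M=2, N=2, n_emb=64, n_heads=4, max_T=small_process.max_T)
    return model.fit(epochs=50, seed=0)


@pytest.fixture(scope="session")
def synthetic_2k(trained_results):
    return trained_results.sample_cohort(2000, seed=1)


def toy_record():
    return PatientRecord(
        labels={"L0"},
        visits=[Visit(codes={"M0", "M3"}), Visit(codes={"M1"})],
    )


@pytest.fixture
def gap_spec():
    return BucketSpec("gap", (0.0, 7.0, 14.0, 30.0), "explicit",
                      ("gap:bucket0", "gap:bucket1", "gap:bucket2"))
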