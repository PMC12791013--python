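"""Shared fixtures.

The trained-model fixtures are session-scoped because desk-scale trainings
take minutes; every test that needs a trained network reuses them.
"""

from __future__ import annotations

import numpy as np
import pytest

from skelimpute import gaps, pipeline, synthetic
from skelimpute.gaps import GapSpec, apply_gaps, apply_switch
from skelimpute.io import Recording, Sample


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sample(rng, L=60, K=8, D=3, missing_frac=0.0) -> Sample:
    coords = rng.normal(0, 10, size=(L, K, D))
    missing = rng.random((L, K)) < missing_frac
    coords[missing] = np.nan
    return Sample("r0", 0, coords, missing)


@pytest.fixture()
def small_recording(rng) -> Recording:
    coords = rng.normal(0, 10, size=(200, 4, 3))
    return Recording("small", 60.0, ["a", "b", "c", "d"], coords)


# ---------------------------------------------------------------------------
# heavy, session-scoped


@pytest.fixture(scope="session")
def desk_data():
    """Oscillatory mouse-like fixture: 12 recordings, by-recording split."""
    return pipeline.desk_dataset(seed=0, n_recordings=12, frames=1000)


@pytest.fixture(scope="session")
def trained_transformer(desk_data):
    model, history = pipeline.desk_train("transformer", desk_data, seed=0)
    return model, history


@pytest.fixture(scope="session")
def trained_gru(desk_data):
    model, history = pipeline.desk_train("gru", desk_data, seed=0)
    return model, history


@pytest.fixture(scope="session")
def hetero_proba():
    """Probabilistic GRU trained on the heteroscedastic fixture, plus
    held-out masked cases with their per-sample noise levels."""
    data = pipeline.desk_dataset(seed=0, n_recordings=18, frames=1560)
    levels = (0.01, 0.05, 0.1)
    noisy_train, _ = synthetic.add_sample_noise(data.train, levels, seed=1)
    noisy_val, _ = synthetic.add_sample_noise(data.val, levels, seed=2)
    noisy_test, test_levels = synthetic.add_sample_noise(data.test, levels,
                                                         seed=3)
    noisy = pipeline.NormalizedSet(noisy_train, noisy_val, noisy_test,
                                   data.test_meta, data.test_orig)
    model, history = pipeline.desk_train("gru", noisy, seed=0, proba=True)
    rng = np.random.default_rng(7)
    cases = []
    for ns in noisy_test:
        L, K, _ = ns.coords.shape
        k = int(rng.integers(0, K))
        ln = int(rng.integers(10, 59))
        st = int(rng.integers(1, L - ln))
        cases.append(apply_gaps(ns, [GapSpec(k, st, ln)]))
    return model, history, cases, test_levels


@pytest.fixture(scope="session")
def switch_twins(desk_data):
    """GRU trained with switch augmentation (prob 0.1) and its switch-free
    twin, plus a seeded switched test set (test-time switch prob 0.5,
    switches involving the masked keypoint, 15-40 frame intervals)."""
    m_sw, _ = pipeline.desk_train("gru", desk_data, seed=0, switch_prob=0.1)
    m_nosw, _ = pipeline.desk_train("gru", desk_data, seed=0, switch_prob=0.0)
    rng = np.random.default_rng(11)
    switched = []
    for ns in desk_data.test:
        L, K, _ = ns.coords.shape
        k = int(rng.integers(0, K))
        ln = int(rng.integers(10, 40))
        st = int(rng.integers(1, L - ln))
        masked = apply_gaps(ns, [GapSpec(k, st, ln)])
        if rng.random() < 0.5:
            b = int(rng.choice([j for j in range(K) if j != k]))
            t0 = int(rng.integers(0, L - 20))
            t1 = int(rng.integers(t0 + 15, min(t0 + 40, L) + 1))
            switched.append(apply_switch(masked, 1.0, rng, force=(k, b, t0, t1)))
    return m_sw, m_nosw, switched
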