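import numpy as np
import pytest

from phytosense.circuit import CircuitComponents, ColeLoadParameters, SweepConfig
from phytosense.dataio import AcquisitionConfig, DatasetContainer, LabeledSample
from phytosense.model import LSTMAttentionClassifier
from phytosense.synth import LightSchedule, default_profile, generate_dataset


@pytest.fixture(scope="session")
def comps():
    return CircuitComponents()


@pytest.fixture(scope="session")
def mid_load():
    return ColeLoadParameters(r0=50e3, r_inf=2e3, tau=2e-6, alpha=0.8)


@pytest.fixture
def small_container():
    """Hand-built 10-sample container with 4 sweeps × 6 points."""
    rng = np.random.default_rng(7)
    samples = [
        LabeledSample(timestamp=float(t),
                      data=rng.integers(0, 65536, size=(4, 6)),
                      label="dark" if t < 5 else "light")
        for t in range(10)
    ]
    return DatasetContainer(samples, {"full_scale": 2.0})


@pytest.fixture(scope="session")
def tiny_burst_dataset():
    """Short synthetic acquisition: 12-min alternating schedule, 5×230."""
    schedule = LightSchedule((("dark", 6.0), ("light", 6.0)))
    acq = AcquisitionConfig(sweeps_per_burst=5)
    profile = default_profile(drift_sd=0.0)
    return schedule, generate_dataset(schedule, profile, acq, seed=5)


def make_separable_toy(n=20, t=4, f=6, gap=3.0, seed=0):
    """Two constant spectra ± a large offset, linearly separable."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(0, 0.1, size=(n, t, f))
    X[y == 1] += gap
    return X, y


@pytest.fixture(scope="session")
def toy_trained_model():
    """Small classifier overfit on the separable toy problem."""
    X, y = make_separable_toy()
    clf = LSTMAttentionClassifier(lstm_units=6, dense_units=4, dropout=0.0,
                                  max_epochs=60, random_state=0)
    clf.fit(X, y)
    return clf, X, y
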