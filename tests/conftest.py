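import numpy as np
import pytest

from freqtag.grids import make_leadfield
from freqtag.simulate import SensorEpochs, SimConfig, simulate_meg


@pytest.fixture(scope="session")
def small_leadfield():
    """Incoherent leadfield: 27-point cubic grid, 12 sensors."""
    return make_leadfield(27, 12, seed=42, mode="random-incoherent")


@pytest.fixture(scope="session")
def shell_leadfield():
    return make_leadfield(50, 30, seed=7, mode="spherical-shell")


@pytest.fixture(scope="session")
def tagged_epochs(small_leadfield):
    """Small tagged simulation: 6 subjects, 5 trials, 32 Hz."""
    cfg = SimConfig(
        seed=3,
        n_subjects=6,
        n_trials=5,
        sfreq=32.0,
        imagery_sources=[(13, 1.2)],
        stimulus_sources=[(2, 1.0), (24, 1.0)],
        noise_sd=0.5,
    )
    imagery, baseline, truth = simulate_meg(cfg, small_leadfield)
    return imagery, baseline, truth


def group_structured_instance(rng, m, n, sparse_k=None, group_size=4):
    """Random incoherent group-L1 instance (unit-norm group blocks)."""
    A = rng.standard_normal((2 * m, group_size * n))
    for i in range(n):
        blk = A[:, group_size * i : group_size * (i + 1)]
        A[:, group_size * i : group_size * (i + 1)] = blk / np.linalg.norm(blk)
    if sparse_k is None:
        b = A @ rng.standard_normal(group_size * n)
    else:
        x = np.zeros(group_size * n)
        for i in rng.choice(n, sparse_k, replace=False):
            x[group_size * i : group_size * (i + 1)] = rng.standard_normal(group_size)
        b = A @ x
    return A, b
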