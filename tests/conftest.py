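import numpy as np
import pytest

import spikefac as sf


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_dataset():
    """A miniature spiking experiment: 2x2 grid, 8 stimuli, 6 reps, 2 s."""
    cfg = sf.ExperimentSimConfig(
        n_rows=2,
        n_cols=2,
        dead_channels=(),
        cycles_per_phase=1,
        reps_per_cycle=2,
        t_gray=0.5,
        t_static=0.5,
        t_moving=1.0,
        background_rate_hz=15.0,
        assemblies=(
            sf.Assembly((0, 1), 8.0, (1.0, 0.8, 0.4, 0.1, 0.1, 0.4, 0.8, 1.0)),
        ),
    )
    return cfg, sf.simulate_experiment(cfg, seed=7)


def random_binned_pair(rng, n=64, p=0.2, bin_width=0.002):
    x = sf.BinnedTrain((rng.random(n) < p).astype(int), bin_width)
    y = sf.BinnedTrain((rng.random(n) < p).astype(int), bin_width)
    return x, y
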