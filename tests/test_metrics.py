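import numpy as np
import pytest

import spikefac as sf
from conftest import random_binned_pair


def make_normalized(values, bin_width=0.002):
    values = np.asarray(values, float)
    L = (values.size - 1) // 2
    return sf.Correlogram(
        np.arange(-L, L + 1), values, bin_width, "normalized"
    )


class TestKappaSync:
    def test_all_negative_clamps_to_zero(self):
        c = make_normalized([-1, -2, -1])
        assert sf.kappa_sync(c, sf.MetricConfig(t_sync=0.002)) == 0.0

    def test_peak_off_centre(self):
        vals = np.zeros(11)
        vals[5 - 2] = 0.7  # lag -2 bins = -4 ms, inside the +-5 ms window
        c = make_normalized(vals)
        assert sf.kappa_sync(c) == pytest.approx(0.7)

    def test_matches_exhaustive_scan(self, rng):
        cfg = sf.MetricConfig(t_sync=0.005)
        for _ in range(50):
            vals = rng.normal(size=21)
            c = make_normalized(vals)
            w = 2  # floor(5 ms / 2 ms)
            want = max(0.0, max(vals[10 - w : 10 + w + 1]))
            assert sf.kappa_sync(c, cfg) == pytest.approx(want, abs=1e-12)

    def test_window_inclusive_in_lag_time(self):
        # lag +-2 bins (= 4 ms) inside; +-3 bins (= 6 ms) outside
        vals = np.zeros(11)
        vals[5 + 3] = 9.0
        vals[5 + 2] = 1.0
        assert sf.kappa_sync(make_normalized(vals)) == pytest.approx(1.0)

    def test_window_exceeding_range_rejected(self):
        c = make_normalized([0, 1, 0])
        with pytest.raises(ValueError):
            sf.kappa_sync(c, sf.MetricConfig(t_sync=0.05))

    def test_requires_normalized_kind(self, rng):
        x, y = random_binned_pair(rng)
        raw = sf.raw_correlogram(x, y, 8)
        with pytest.raises(ValueError):
            sf.kappa_sync(raw)

    def test_argmax_lag_tie_break(self):
        vals = np.zeros(11)
        vals[5 - 1] = vals[5 + 1] = 2.0
        assert sf.kappa_sync_lag(make_normalized(vals)) == -1


class TestKappaOscSync:
    def test_full_band_is_one(self, rng):
        vals = rng.normal(size=25)
        c = make_normalized(vals)
        cfg = sf.MetricConfig(f_min=0.0, f_max=250.0)  # full Nyquist range
        assert sf.kappa_oscsync(c, cfg) == pytest.approx(1.0, abs=1e-12)

    def test_pure_tone_concentrates(self):
        """A zero-mean 40 Hz cosine sampled at 2 ms over an integer
        number of cycles puts all power in the 30-50 Hz band."""
        n = 25  # 50 ms = 2 cycles of 40 Hz; bin index 2
        t = np.arange(n) * 0.002
        vals = np.cos(2 * np.pi * 40.0 * t)
        L = 12
        c = sf.Correlogram(np.arange(-L, L + 1), vals, 0.002, "normalized")
        assert sf.kappa_oscsync(c, sf.MetricConfig()) == pytest.approx(
            1.0, abs=1e-9
        )

    def test_constant_vector_band_excluding_dc(self):
        c = make_normalized(np.ones(25))
        assert sf.kappa_oscsync(c, sf.MetricConfig()) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_bounds_on_random_correlograms(self, rng):
        cfg = sf.MetricConfig()
        for _ in range(50):
            c = make_normalized(rng.normal(size=41))
            k = sf.kappa_oscsync(c, cfg)
            assert 0.0 <= k <= 1.0

    def test_parseval_consistency(self, rng):
        """Total DFT power equals N * sum lambda(t)^2."""
        vals = rng.normal(size=31)
        spec = np.abs(np.fft.fft(vals)) ** 2
        assert spec.sum() == pytest.approx(31 * np.sum(vals**2), rel=1e-9)

    def test_zero_correlogram_rejected(self):
        c = make_normalized(np.zeros(11))
        with pytest.raises(ValueError):
            sf.kappa_oscsync(c)

    def test_band_above_nyquist_rejected(self):
        c = make_normalized(np.ones(11))
        with pytest.raises(ValueError):
            sf.kappa_oscsync(c, sf.MetricConfig(f_min=100.0, f_max=400.0))


class TestMetricTable:
    def test_batched_equals_per_pair_reference(self, small_dataset):
        """The FFT-batched pipeline path reproduces the per-pair
        correlogram functions to machine precision."""
        _, ds = small_dataset
        cfg = sf.MetricConfig()
        table = sf.compute_metric_table(ds, cfg)
        assert len(table) == 6 * 8 * 6  # pairs x stimuli x reps
        sub = table.sample(40, random_state=0)
        for row in sub.itertuples():
            a, b = map(int, row.pair.split("-"))
            x = sf.bin_spike_train(ds.train(a, row.stimulus, row.repetition))
            y = sf.bin_spike_train(ds.train(b, row.stimulus, row.repetition))
            c = sf.normalized_correlogram(x, y)
            assert sf.kappa_sync(c, cfg) == pytest.approx(
                row.kappa_sync, abs=1e-9
            )
            if not np.allclose(c.values, 0):
                assert sf.kappa_oscsync(c, cfg) == pytest.approx(
                    row.kappa_oscsync, abs=1e-9
                )

    def test_window_restricts_analysis_epoch(self, small_dataset):
        """A window covering the whole trial reproduces the default; a
        sub-epoch window counts only coincidences inside it."""
        _, ds = small_dataset
        full = sf.compute_metric_table(ds)
        same = sf.compute_metric_table(ds, window=(0.0, ds.duration))
        np.testing.assert_allclose(
            same.kappa_sync.to_numpy(), full.kappa_sync.to_numpy()
        )
        moving = sf.compute_metric_table(ds, window=(1.0, 2.0))
        assert len(moving) == len(full)
        # coincidence counts scale with the analysed duration
        assert moving.kappa_sync.mean() < full.kappa_sync.mean()
        with pytest.raises(ValueError):
            sf.compute_metric_table(ds, window=(1.0, 99.0))

    def test_synchrony_increases_with_injection(self):
        """kappa_sync grows with the injected coincidence rate
        (monotone in expectation)."""
        means = []
        for rate in (0.0, 5.0, 15.0):
            cfg = sf.ExperimentSimConfig(
                n_rows=1, n_cols=2, dead_channels=(),
                cycles_per_phase=1, reps_per_cycle=3,
                t_gray=0.5, t_static=0.5, t_moving=1.0,
                background_rate_hz=15.0,
                assemblies=(
                    sf.Assembly((0, 1), rate, (1.0,) * 8, (1, 1, 1)),
                ),
            )
            ds = sf.simulate_experiment(cfg, seed=11)
            means.append(sf.compute_metric_table(ds).kappa_sync.mean())
        assert means[0] < means[1] < means[2]
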