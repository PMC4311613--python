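import numpy as np
import pytest
from scipy import stats

import spikefac as sf


class TestSimulateTensor:
    def test_zero_noise_exact_rank(self):
        tensor, _ = sf.simulate_tensor(
            sf.TensorSimConfig(noise_sd=0.0), seed=0
        )
        m = sf.als_fit(tensor, 3, n_starts=3, seed=0, tol=1e-12)
        rel_resid = 1 - m.explained_variance_pct / 100
        assert rel_resid < 1e-8

    def test_bitwise_reproducible(self):
        t1, l1 = sf.simulate_tensor(sf.TensorSimConfig(), seed=123)
        t2, l2 = sf.simulate_tensor(sf.TensorSimConfig(), seed=123)
        np.testing.assert_array_equal(t1.values, t2.values)
        for a, b in zip(l1, l2):
            np.testing.assert_array_equal(a, b)

    def test_noise_moment_check(self):
        """Empirical SD of X - signal matches the configured sigma
        within 5% at >= 10^4 entries."""
        cfg = sf.TensorSimConfig(shape=(25, 25, 25), noise_sd=0.2)
        tensor, (A, B, C) = sf.simulate_tensor(cfg, seed=9)
        signal = np.einsum("if,jf,kf->ijk", A, B, C)
        noise = tensor.values - signal
        assert noise.std() == pytest.approx(0.2 * signal.std(), rel=0.05)

    def test_separation_infeasible_raises(self):
        cfg = sf.TensorSimConfig(
            shape=(2, 2, 2), rank=2, max_congruence=0.001, max_retries=5
        )
        with pytest.raises(RuntimeError):
            sf.simulate_tensor(cfg, seed=0)


class TestExperimentSchedule:
    def test_default_schedule_counts(self):
        cfg = sf.ExperimentSimConfig()
        assert cfg.n_stimuli == 8
        assert cfg.n_repetitions == 63
        assert cfg.duration == 8.0
        labels = [cfg.phase_of(r) for r in range(1, 64)]
        assert labels[:21] == [0] * 21
        assert labels[21:42] == [1] * 21
        assert labels[42:] == [2] * 21

    def test_generated_dataset_structure(self, small_dataset):
        cfg, ds = small_dataset
        assert len(ds.stimulus_ids) == 8
        assert len(ds.repetitions) == cfg.n_repetitions
        phases = [ds.phase_labels[r] for r in ds.repetitions]
        per = cfg.cycles_per_phase * cfg.reps_per_cycle
        assert phases[:per] == ["warm"] * per
        assert phases[per : 2 * per] == ["deactivation"] * per
        assert phases[2 * per :] == ["rewarm"] * per

    def test_pure_function_of_seed(self, small_dataset):
        cfg, ds = small_dataset
        again = sf.simulate_experiment(cfg, seed=7)
        for key in ds.trains:
            np.testing.assert_array_equal(
                again.trains[key].times, ds.trains[key].times
            )


class TestInjectedSynchrony:
    @staticmethod
    def null_config(rate):
        return sf.ExperimentSimConfig(
            n_rows=2, n_cols=2, dead_channels=(),
            cycles_per_phase=1, reps_per_cycle=3,
            t_gray=0.5, t_static=0.5, t_moving=1.0,
            background_rate_hz=20.0,
            assemblies=(
                sf.Assembly((0, 1), rate, (1.0,) * 8, (1.0, 0.3, 1.0)),
            ),
        )

    def test_no_injection_null_synchrony(self):
        """With zero injection the jitter-corrected kappa_sync averages
        to its max-statistic bias level identically across pairs: the
        injected-pair mean minus the never-injected-pair mean is within
        3 SE of 0 over seeds."""
        diffs = []
        for seed in range(30):
            ds = sf.simulate_experiment(self.null_config(0.0), seed=seed)
            tab = sf.compute_metric_table(ds)
            inj = tab[tab.pair == "0-1"].kappa_sync.mean()
            rest = tab[tab.pair != "0-1"].kappa_sync.mean()
            diffs.append(inj - rest)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) < 3 * se + 1e-12

    def test_deactivation_dip_direction(self):
        """Deactivation multiplier 0.3 lowers kappa_sync on injected
        pairs during repetitions of the deactivation phase (rank test
        over 20 seeds, p < 0.01)."""
        warm_means, deact_means = [], []
        for seed in range(20):
            ds = sf.simulate_experiment(self.null_config(10.0), seed=seed)
            tab = sf.compute_metric_table(ds)
            sub = tab[tab.pair == "0-1"]
            phase = {r: ds.phase_labels[r] for r in ds.repetitions}
            lab = sub.repetition.map(phase)
            warm_means.append(sub[lab == "warm"].kappa_sync.mean())
            deact_means.append(sub[lab == "deactivation"].kappa_sync.mean())
        p = stats.wilcoxon(
            warm_means, deact_means, alternative="greater"
        ).pvalue
        assert p < 0.01

    def test_oscillation_raises_band_power(self):
        """40 Hz co-modulation raises kappa_oscsync (30-50 Hz) for
        co-modulated pairs above non-modulated pairs."""
        cfg = sf.ExperimentSimConfig(
            n_rows=2, n_cols=3, dead_channels=(),
            cycles_per_phase=1, reps_per_cycle=4,
            t_gray=1.0, t_static=1.0, t_moving=2.0,
            background_rate_hz=30.0, assemblies=(),
            osc_depth=0.8, osc_channels=(0, 1, 2, 3),
        )
        ds = sf.simulate_experiment(cfg, seed=0)
        tab = sf.compute_metric_table(ds)
        mod_pairs = {"0-1", "0-2", "0-3", "1-2", "1-3", "2-3"}
        mod = tab[tab.pair.isin(mod_pairs)].kappa_oscsync
        non = tab[tab.pair == "4-5"].kappa_oscsync
        p = stats.mannwhitneyu(mod, non, alternative="greater").pvalue
        assert p < 0.01

    def test_assembly_validation(self):
        with pytest.raises(ValueError, match="n_stimuli"):
            sf.simulate_experiment(
                sf.ExperimentSimConfig(
                    assemblies=(sf.Assembly((0, 1), 1.0, (1.0,) * 4),)
                ),
                seed=0,
            )
        with pytest.raises(ValueError, match="live"):
            sf.simulate_experiment(
                sf.ExperimentSimConfig(
                    assemblies=(sf.Assembly((5, 1), 1.0, (1.0,) * 8),)
                ),
                seed=0,
            )

    def test_implausible_injection_warns(self):
        cfg = self.null_config(100.0)
        with pytest.warns(RuntimeWarning, match="background"):
            sf.simulate_experiment(cfg, seed=0)


class TestEndToEndRecovery:
    def test_planted_rank_and_loadings_recovered(self):
        """Full pipeline on the default-geometry emulation: component
        selection finds the three planted assemblies and the pair-mode
        loadings match the planted membership patterns (congruence
        >= 0.9)."""
        cfg = sf.ExperimentSimConfig()
        ds = sf.simulate_experiment(cfg, seed=1)
        tab = sf.compute_metric_table(ds)
        tens = sf.center_tensor(sf.build_tensor(tab))
        rep = sf.select_components(tens, f_max=6, seed=0, n_starts=4)
        assert rep.chosen == 3
        P = sf.planted_pair_loadings(cfg, sf.enumerate_pairs(ds.grid))
        cc = np.abs(sf.congruence_matrix(P, rep.models[3].A))
        assert cc.max(axis=1).min() >= 0.9
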