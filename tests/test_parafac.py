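import numpy as np
import pytest

import spikefac as sf
from spikefac.parafac import ParafacModel, max_offdiag_congruence


def triple_loop_reconstruct(A, B, C):
    """Independent elementwise oracle for the trilinear model."""
    I, J, K = A.shape[0], B.shape[0], C.shape[0]
    F = A.shape[1]
    out = np.zeros((I, J, K))
    for i in range(I):
        for j in range(J):
            for k in range(K):
                for f in range(F):
                    out[i, j, k] += A[i, f] * B[j, f] * C[k, f]
    return out


class TestReconstruct:
    def test_scalar_case(self):
        m = ParafacModel(np.array([[2.0]]), np.array([[3.0]]),
                         np.array([[4.0]]), 1)
        assert sf.reconstruct(m)[0, 0, 0] == pytest.approx(24.0)

    def test_zero_loadings(self):
        m = ParafacModel(np.zeros((3, 2)), np.ones((4, 2)), np.ones((5, 2)), 2)
        assert np.all(sf.reconstruct(m) == 0)

    def test_matches_triple_loop(self, rng):
        A, B, C = rng.normal(size=(4, 2)), rng.normal(size=(3, 2)), \
            rng.normal(size=(5, 2))
        m = ParafacModel(A, B, C, 2)
        np.testing.assert_allclose(
            sf.reconstruct(m), triple_loop_reconstruct(A, B, C), atol=1e-12
        )


class TestExplainedVariance:
    def test_perfect_and_zero_model(self, rng):
        A, B, C = rng.normal(size=(4, 2)), rng.normal(size=(3, 2)), \
            rng.normal(size=(5, 2))
        m = ParafacModel(A, B, C, 2)
        X = sf.reconstruct(m)
        assert sf.explained_variance(m, X) == pytest.approx(100.0)
        zero = ParafacModel(np.zeros((4, 2)), B, C, 2)
        assert sf.explained_variance(zero, X) == pytest.approx(0.0)

    def test_matches_direct_formula(self, rng):
        A, B, C = rng.normal(size=(4, 2)), rng.normal(size=(3, 2)), \
            rng.normal(size=(5, 2))
        m = ParafacModel(A, B, C, 2)
        X = rng.normal(size=(4, 3, 5))
        direct = 100 * (
            1 - np.sum((X - sf.reconstruct(m)) ** 2) / np.sum(X**2)
        )
        assert sf.explained_variance(m, X) == pytest.approx(direct, abs=1e-10)

    def test_zero_tensor_rejected(self, rng):
        m = ParafacModel(np.ones((2, 1)), np.ones((2, 1)), np.ones((2, 1)), 1)
        with pytest.raises(ValueError):
            sf.explained_variance(m, np.zeros((2, 2, 2)))


class TestCongruence:
    def test_orthogonal_and_duplicate_columns(self):
        A = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = ParafacModel(A, A, A, 2)
        comb = sf.component_congruence(m)["combined"]
        assert comb[0, 1] == pytest.approx(0.0)
        dup = np.array([[1.0, 1.0], [2.0, 2.0]])
        m2 = ParafacModel(dup, dup, dup, 2)
        assert sf.component_congruence(m2)["combined"][0, 1] == pytest.approx(
            1.0
        )

    def test_matches_cosine_loop(self, rng):
        A, B, C = (rng.normal(size=(6, 3)) for _ in range(3))
        m = ParafacModel(A, B, C, 3)
        got = sf.component_congruence(m)
        for M, key in ((A, "pair"), (B, "stimulus"), (C, "repetition")):
            want = np.zeros((3, 3))
            for f in range(3):
                for g in range(3):
                    want[f, g] = M[:, f] @ M[:, g] / (
                        np.linalg.norm(M[:, f]) * np.linalg.norm(M[:, g])
                    )
            np.testing.assert_allclose(got[key], want, atol=1e-12)
        np.testing.assert_allclose(
            got["combined"], got["pair"] * got["stimulus"] * got["repetition"],
            atol=1e-12,
        )

    def test_zero_column_rejected(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0]])
        m = ParafacModel(A, A, A, 2)
        with pytest.raises(ValueError):
            sf.component_congruence(m)


class TestAlsFit:
    def test_rank1_recovery(self, rng):
        a, b, c = rng.uniform(1, 2, 4), rng.uniform(1, 2, 3), \
            rng.uniform(1, 2, 5)
        X = np.einsum("i,j,k->ijk", a, b, c)
        m = sf.als_fit(X, 1, n_starts=2, seed=0)
        truth = ParafacModel(a[:, None], b[:, None], c[:, None], 1)
        fms = sf.factor_match_score(
            truth, m, modes=("pair", "stimulus", "repetition")
        )
        assert fms >= 0.9999

    def test_noiseless_rank3_recovery(self):
        """Construct-then-recover: >= 99.99% EV and factor match >= 0.99
        across 20 seeds (uniqueness of the trilinear decomposition)."""
        n_good = 0
        for seed in range(20):
            tensor, (A, B, C) = sf.simulate_tensor(
                sf.TensorSimConfig(noise_sd=0.0), seed=seed
            )
            m = sf.als_fit(tensor, 3, n_starts=4, seed=seed)
            truth = ParafacModel(A, B, C, 3)
            fms = sf.factor_match_score(
                truth, m, modes=("pair", "stimulus", "repetition")
            )
            if m.explained_variance_pct >= 99.99 and fms >= 0.99:
                n_good += 1
        assert n_good == 20

    def test_residual_monotone_nonincreasing(self, rng):
        X = rng.normal(size=(6, 5, 7))
        m = sf.als_fit(X, 3, n_starts=3, seed=1)
        diffs = np.diff(m.residual_history)
        assert np.all(diffs <= 1e-10 * np.sum(X**2))

    def test_reconstruction_invariant_under_normalization(self, rng):
        """The scale/sign convention does not change the fitted surface:
        reconstructing the normalized model reproduces the tensor to
        the fitted accuracy."""
        tensor, _ = sf.simulate_tensor(
            sf.TensorSimConfig(noise_sd=0.0), seed=3
        )
        m = sf.als_fit(tensor, 3, n_starts=3, seed=0)
        np.testing.assert_allclose(
            sf.reconstruct(m), tensor.values, atol=1e-3
        )
        # convention actually holds
        np.testing.assert_allclose(np.linalg.norm(m.B, axis=0), 1.0, atol=1e-9)
        np.testing.assert_allclose(np.linalg.norm(m.C, axis=0), 1.0, atol=1e-9)

    def test_components_ordered_by_contribution(self, rng):
        tensor, _ = sf.simulate_tensor(sf.TensorSimConfig(noise_sd=0.05),
                                       seed=5)
        m = sf.als_fit(tensor, 3, n_starts=3, seed=0)
        norms = np.linalg.norm(m.A, axis=0)
        assert np.all(np.diff(norms) <= 1e-9)

    def test_determinism_given_seed(self):
        tensor, _ = sf.simulate_tensor(sf.TensorSimConfig(), seed=2)
        m1 = sf.als_fit(tensor, 2, n_starts=3, seed=42)
        m2 = sf.als_fit(tensor, 2, n_starts=3, seed=42)
        np.testing.assert_array_equal(m1.A, m2.A)
        np.testing.assert_array_equal(m1.C, m2.C)

    def test_invalid_inputs(self, rng):
        X = rng.normal(size=(3, 3, 3))
        with pytest.raises(ValueError):
            sf.als_fit(X, 0)
        with pytest.raises(ValueError):
            sf.als_fit(X, 10)
        X[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            sf.als_fit(X, 1)

    def test_multistart_reports_all_fits(self):
        tensor, _ = sf.simulate_tensor(sf.TensorSimConfig(), seed=2)
        m = sf.als_fit(tensor, 2, n_starts=5, seed=0)
        assert len(m.start_fits) == 5
        assert max_offdiag_congruence(m) <= 1.0
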