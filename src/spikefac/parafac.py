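"""Trilinear PARAFAC (canonical polyadic) decomposition by alternating
least squares.

The model represents a 3-way array X (I x J x K) as

    x_ijk = sum_{f=1..F} a_if * b_jf * c_kf + eps_ijk,

with loading matrices A (I x F), B (J x F), C (K x F).  ALS cycles
conditional least-squares updates of A, B and C until the fit stops
improving.  Under mild conditions (k-rank inequality) the solution is
unique up to component permutation and scaling — unlike PCA, which has
rotational freedom.

Conventions adopted here (the model itself does not fix them):

* columns of B and C are scaled to unit norm, magnitudes absorbed into A;
* the sign of each B and C column is flipped so its largest-magnitude
  entry is positive, the flips absorbed into A;
* components are ordered by their contribution ||a_f|| (descending) —
  cosmetic only, the model has no inherent component order;
* random uniform [0, 1) initialisation with multi-start, keeping the
  best-fit run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import khatri_rao

from .tensor import SynchronyTensor

__all__ = [
    "ParafacModel",
    "als_fit",
    "reconstruct",
    "explained_variance",
    "component_congruence",
    "congruence_matrix",
]

DEGENERACY_THRESHOLD = -0.85


@dataclass
class ParafacModel:
    """A fitted rank-F trilinear model with diagnostics."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    n_components: int
    explained_variance_pct: float = np.nan
    iterations: int = 0
    converged: bool = False
    seed: int | None = None
    residual_history: np.ndarray | None = None
    start_fits: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        F = self.n_components
        for name, M in (("A", self.A), ("B", self.B), ("C", self.C)):
            M = np.asarray(M, dtype=float)
            setattr(self, name, M)
            if M.ndim != 2 or M.shape[1] != F:
                raise ValueError(f"loading matrix {name} must have {F} columns")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.A.shape[0], self.B.shape[0], self.C.shape[0])


def _as_array(X) -> np.ndarray:
    if isinstance(X, SynchronyTensor):
        return X.values
    return np.asarray(X, dtype=float)


def reconstruct(model: ParafacModel) -> np.ndarray:
    """x_hat_ijk = sum_f a_if b_jf c_kf."""
    return np.einsum("if,jf,kf->ijk", model.A, model.B, model.C)


def explained_variance(model: ParafacModel, X) -> float:
    """100 * (1 - ||X - x_hat||^2 / ||X||^2)."""
    X = _as_array(X)
    total = float(np.sum(X**2))
    if total == 0:
        raise ValueError("explained variance undefined for a zero tensor")
    resid = float(np.sum((X - reconstruct(model)) ** 2))
    return 100.0 * (1.0 - resid / total)


def congruence_matrix(U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Tucker congruence (cosine) between columns of U and columns of V."""
    nu = np.linalg.norm(U, axis=0)
    nv = np.linalg.norm(V, axis=0)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("congruence undefined for a zero-norm column")
    return (U.T @ V) / np.outer(nu, nv)


def component_congruence(model: ParafacModel) -> dict[str, np.ndarray]:
    """Per-mode Tucker congruence matrices and their elementwise product.

    The combined matrix is the standard proxy for "correlated
    components": entries near +-1 off the diagonal flag components that
    duplicate (or degenerately cancel) each other.
    """
    phi_a = congruence_matrix(model.A, model.A)
    phi_b = congruence_matrix(model.B, model.B)
    phi_c = congruence_matrix(model.C, model.C)
    return {
        "pair": phi_a,
        "stimulus": phi_b,
        "repetition": phi_c,
        "combined": phi_a * phi_b * phi_c,
    }


def max_offdiag_congruence(model: ParafacModel) -> float:
    """max |combined congruence| off the diagonal; 0 for F = 1."""
    if model.n_components < 2:
        return 0.0
    combined = component_congruence(model)["combined"]
    off = combined[~np.eye(model.n_components, dtype=bool)]
    return float(np.max(np.abs(off)))


def _normalize(A: np.ndarray, B: np.ndarray, C: np.ndarray):
    """Unit-norm B and C columns, sign-fixed, magnitude into A; order by
    component contribution ||a_f|| descending."""
    A, B, C = A.copy(), B.copy(), C.copy()
    for M in (B, C):
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        M /= norms
        A *= norms
        signs = np.sign(M[np.argmax(np.abs(M), axis=0), np.arange(M.shape[1])])
        signs[signs == 0] = 1.0
        M *= signs
        A *= signs
    order = np.argsort(-np.linalg.norm(A, axis=0), kind="stable")
    return A[:, order], B[:, order], C[:, order]


def _solve_mode(unfolded: np.ndarray, U: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Conditional least squares for one loading matrix.

    ``unfolded`` is the mode-n matricization (C order: remaining modes
    with the later one varying fastest); U, V the other two loading
    matrices in that same order.
    """
    Z = khatri_rao(U, V)                       # rows: (u index) x (v index)
    G = (U.T @ U) * (V.T @ V)
    rhs = unfolded @ Z
    try:
        return np.linalg.solve(G.T, rhs.T).T
    except np.linalg.LinAlgError:
        warnings.warn(
            "rank-deficient conditional system in ALS update; "
            "falling back to pseudoinverse",
            RuntimeWarning,
            stacklevel=2,
        )
        return rhs @ np.linalg.pinv(G)


def _als_single(
    X: np.ndarray, F: int, rng: np.random.Generator, tol: float, max_iter: int
):
    I, J, K = X.shape
    X0 = X.reshape(I, J * K)
    X1 = np.moveaxis(X, 1, 0).reshape(J, I * K)
    X2 = np.moveaxis(X, 2, 0).reshape(K, I * J)
    total = float(np.sum(X**2))

    B = rng.uniform(size=(J, F))
    C = rng.uniform(size=(K, F))
    A = _solve_mode(X0, B, C)

    residuals = []
    prev = np.inf
    converged = False
    for it in range(1, max_iter + 1):
        A = _solve_mode(X0, B, C)
        B = _solve_mode(X1, A, C)
        C = _solve_mode(X2, A, B)
        xhat0 = A @ khatri_rao(B, C).T
        resid = float(np.sum((X0 - xhat0) ** 2))
        residuals.append(resid)
        if prev - resid < tol * max(total, 1e-300):
            converged = True
            break
        prev = resid
    return A, B, C, np.array(residuals), converged


def als_fit(
    X,
    n_components: int,
    n_starts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 2000,
    seed: int | None = None,
) -> ParafacModel:
    """Fit a rank-F PARAFAC model by multi-start alternating least squares.

    Parameters
    ----------
    X
        3-way array or :class:`SynchronyTensor`.
    n_components
        F, the number of trilinear components.
    n_starts
        Independent random initialisations; the best-fit run is kept.
    tol
        Convergence threshold on the decrease of the residual sum of
        squares, relative to ||X||^2.
    max_iter
        Iteration cap per start.
    seed
        Seeds the random initialisations; fits are reproducible given
        (seed, config).
    """
    Xv = _as_array(X)
    if Xv.ndim != 3:
        raise ValueError("PARAFAC input must be a 3-way array")
    if not np.all(np.isfinite(Xv)):
        raise ValueError("PARAFAC input contains non-finite values")
    F = int(n_components)
    I, J, K = Xv.shape
    if F < 1:
        raise ValueError("n_components must be >= 1")
    if F > min(I * J, J * K, I * K):
        raise ValueError(
            f"n_components={F} infeasible for tensor of shape {Xv.shape}"
        )

    ss = np.random.SeedSequence(seed)
    best = None
    fits = []
    for child in ss.spawn(n_starts):
        rng = np.random.default_rng(child)
        A, B, C, residuals, converged = _als_single(Xv, F, rng, tol, max_iter)
        resid = residuals[-1] if residuals.size else np.inf
        fits.append(resid)
        if best is None or resid < best[3][-1]:
            best = (A, B, C, residuals, converged)

    A, B, C, residuals, converged = best
    A, B, C = _normalize(A, B, C)
    model = ParafacModel(
        A,
        B,
        C,
        F,
        iterations=int(residuals.size),
        converged=converged,
        seed=seed,
        residual_history=residuals,
        start_fits=tuple(fits),
    )
    model.explained_variance_pct = explained_variance(model, Xv)
    if F >= 2:
        combined = component_congruence(model)["combined"]
        off = combined[~np.eye(F, dtype=bool)]
        if off.size and float(np.min(off)) < DEGENERACY_THRESHOLD:
            warnings.warn(
                "PARAFAC solution shows two-factor degeneracy "
                f"(combined congruence {float(np.min(off)):.3f})",
                RuntimeWarning,
                stacklevel=2,
            )
    return model
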