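"""Model stability checks: split-half experiments and a
residual-bootstrap sensitivity analysis.

Split-half: the tensor is partitioned along the repetition mode into
odd- and even-indexed trials, PARAFAC is fitted to each half
independently, and the pair/stimulus loadings are compared after
aligning components.  Similar loadings (factor-match score near 1) and
similar explained variances indicate a stable, applicable model.

Residual bootstrap: ALS least-squares fitting is optimal under Gaussian
errors, an assumption spike-synchrony residuals need not satisfy.  The
procedure compares refits under two error sets — residuals resampled
from the empirical residual distribution vs draws from a Gaussian
fitted to it — added to the model reconstruction; similar factor-match
score distributions mean the solution is insensitive to the error
distribution's shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .parafac import ParafacModel, als_fit, congruence_matrix, reconstruct
from .tensor import SynchronyTensor

__all__ = [
    "SplitHalfResult",
    "BootstrapResult",
    "factor_match_score",
    "split_half",
    "residual_bootstrap",
]

_MODE_ATTR = {"pair": "A", "stimulus": "B", "repetition": "C"}


def align_components(
    model_ref: ParafacModel,
    model: ParafacModel,
    modes: Sequence[str] = ("pair", "stimulus"),
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy component matching between two models.

    Returns (permutation, scores): ``permutation[f]`` is the component
    of ``model`` matched to component f of ``model_ref`` and
    ``scores[f]`` the combined congruence (product over ``modes``) of
    that match.  Matching is greedy on |combined congruence|,
    descending.

    Sign handling: a trilinear component is invariant under flipping
    the sign of two of its three loading vectors at once.  When
    ``modes`` omits at least one mode (e.g. the repetition mode in a
    split-half comparison), a sign flip in one compared mode can always
    be paired with a flip in an uncompared mode, so the sign of the
    product is not identifiable and the absolute value is returned.
    With all three modes compared the product is flip-invariant and
    kept signed.
    """
    if model_ref.n_components != model.n_components:
        raise ValueError("models must share the number of components")
    F = model_ref.n_components
    combined = np.ones((F, F))
    for mode in modes:
        U = getattr(model_ref, _MODE_ATTR[mode])
        V = getattr(model, _MODE_ATTR[mode])
        combined = combined * congruence_matrix(U, V)
    signed = len(set(modes)) >= 3
    perm = np.full(F, -1, dtype=int)
    scores = np.zeros(F)
    work = np.abs(combined).copy()
    for _ in range(F):
        f, g = np.unravel_index(np.argmax(work), work.shape)
        perm[f] = g
        scores[f] = combined[f, g] if signed else abs(combined[f, g])
        work[f, :] = -np.inf
        work[:, g] = -np.inf
    return perm, scores


def factor_match_score(
    model_ref: ParafacModel,
    model: ParafacModel,
    modes: Sequence[str] = ("pair", "stimulus"),
) -> float:
    """Mean combined congruence of optimally matched components; 1 for
    identical models (up to permutation and model-equivalent sign
    flips).  In [0, 1] when ``modes`` is a proper subset of the three
    modes (sign unidentifiable, see :func:`align_components`), else in
    [-1, 1]."""
    _, scores = align_components(model_ref, model, modes)
    return float(np.mean(scores))


@dataclass
class SplitHalfResult:
    model_odd: ParafacModel
    model_even: ParafacModel
    permutation: np.ndarray
    component_scores: np.ndarray
    factor_match: float
    explained_variance_odd: float
    explained_variance_even: float


def split_half(
    X,
    n_components: int,
    scheme: Literal["odd_even"] = "odd_even",
    n_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> SplitHalfResult:
    """Independent PARAFAC fits on odd- and even-numbered repetitions.

    Splitting by repetition-index parity interleaves the experiment's
    phases, so both halves sample warm, deactivation and rewarm trials
    alike.  The pair and stimulus loadings of both fits are aligned and
    scored; the repetition loadings live on different trials and are
    not compared.
    """
    if scheme != "odd_even":
        raise ValueError(f"unknown split scheme {scheme!r}")
    if isinstance(X, SynchronyTensor):
        values = X.values
        reps = np.asarray(X.repetitions)
    else:
        values = np.asarray(X, dtype=float)
        reps = np.arange(1, values.shape[2] + 1)  # 1-based trial numbers
    if values.shape[2] < 4:
        raise ValueError("need at least 4 repetitions to split")
    odd_mask = reps % 2 == 1
    X_odd = values[:, :, odd_mask]
    X_even = values[:, :, ~odd_mask]

    seeds = (None, None) if seed is None else tuple(
        int(s.generate_state(1)[0] % 2**31)
        for s in np.random.SeedSequence(seed).spawn(2)
    )
    model_odd = als_fit(X_odd, n_components, n_starts=n_starts, tol=tol,
                        max_iter=max_iter, seed=seeds[0])
    model_even = als_fit(X_even, n_components, n_starts=n_starts, tol=tol,
                         max_iter=max_iter, seed=seeds[1])
    perm, scores = align_components(model_odd, model_even)
    return SplitHalfResult(
        model_odd=model_odd,
        model_even=model_even,
        permutation=perm,
        component_scores=scores,
        factor_match=float(np.mean(scores)),
        explained_variance_odd=model_odd.explained_variance_pct,
        explained_variance_even=model_even.explained_variance_pct,
    )


@dataclass
class BootstrapResult:
    baseline: ParafacModel
    scores_empirical: np.ndarray
    scores_gaussian: np.ndarray
    residual_mean: float
    residual_sd: float


def residual_bootstrap(
    X,
    model: ParafacModel,
    n_reps: int = 50,
    seed: int | None = None,
    target: Literal["reconstruction", "data"] = "reconstruction",
    n_starts: int = 3,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> BootstrapResult:
    """Sensitivity of the PARAFAC solution to the error distribution.

    Residuals eps = X - x_hat are taken from the fitted baseline.  Two
    error sets of ``n_reps`` replicates each are generated: (1) values
    resampled with replacement from the empirical residual distribution
    and (2) draws from Normal(mean(eps), sd(eps)).  Each replicate adds
    its errors to the baseline reconstruction (``target="data"`` adds
    them to the data instead, i.e. signal plus doubled noise), refits,
    and records the factor-match score to the baseline over all three
    modes.  Similar score distributions for the two sets indicate
    robustness to non-Gaussian errors.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    Xv = X.values if isinstance(X, SynchronyTensor) else np.asarray(X, float)
    xhat = reconstruct(model)
    eps = Xv - xhat
    base = Xv if target == "data" else xhat
    mu, sd = float(np.mean(eps)), float(np.std(eps))

    rng = np.random.default_rng(seed)
    fit_seed = np.random.SeedSequence(seed).generate_state(1)[0] % 2**31
    scores = {"empirical": [], "gaussian": []}
    for r in range(n_reps):
        draws = {
            "empirical": rng.choice(eps.ravel(), size=eps.shape, replace=True),
            "gaussian": rng.normal(mu, sd, size=eps.shape),
        }
        for kind, err in draws.items():
            refit = als_fit(
                base + err,
                model.n_components,
                n_starts=n_starts,
                tol=tol,
                max_iter=max_iter,
                seed=int((fit_seed + r) % 2**31),
            )
            scores[kind].append(
                factor_match_score(
                    model, refit, modes=("pair", "stimulus", "repetition")
                )
            )
    return BootstrapResult(
        baseline=model,
        scores_empirical=np.array(scores["empirical"]),
        scores_gaussian=np.array(scores["gaussian"]),
        residual_mean=mu,
        residual_sd=sd,
    )
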