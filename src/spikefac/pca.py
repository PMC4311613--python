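"""Bilinear baseline: unfold the 3-way tensor and run PCA.

PCA is inherently bilinear; applying it to a trilinear array requires
matricizing (unfolding) the array along one mode, which discards the
true three-way structure.  On genuinely trilinear data an F-component
PARAFAC therefore matches or beats PCA component-for-component, and
PCA needs more components to reach the same cumulative variance — the
quantitative argument for the multiway model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .tensor import SynchronyTensor

__all__ = [
    "PcaModel",
    "unfold",
    "fold",
    "pca_fit",
    "pca_on_tensor",
    "components_needed",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, SynchronyTensor):
        return X.values
    return np.asarray(X, dtype=float)


def unfold(X, mode: int) -> np.ndarray:
    """Mode-n matricization (1-based mode in {1, 2, 3}).

    Rows are indexed by the chosen mode; columns by the remaining two
    modes in increasing mode order, the later mode varying fastest
    (C order).  E.g. mode 3 of a (105, 8, 63) tensor gives (63, 840).
    """
    Xv = _as_array(X)
    if mode not in (1, 2, 3):
        raise ValueError("mode must be 1, 2 or 3")
    return np.moveaxis(Xv, mode - 1, 0).reshape(Xv.shape[mode - 1], -1)


def fold(M: np.ndarray, mode: int, shape: tuple[int, int, int]) -> np.ndarray:
    """Inverse of :func:`unfold` for a tensor of the given shape."""
    if mode not in (1, 2, 3):
        raise ValueError("mode must be 1, 2 or 3")
    rest = [s for i, s in enumerate(shape) if i != mode - 1]
    return np.moveaxis(
        np.asarray(M).reshape(shape[mode - 1], *rest), 0, mode - 1
    )


@dataclass
class PcaModel:
    """Column-centered SVD principal component analysis of an unfolding."""

    scores: np.ndarray          # observations x components
    loadings: np.ndarray        # variables x components
    explained_variance: np.ndarray
    explained_variance_pct: np.ndarray
    mode: int | None = None

    @property
    def cumulative_variance_pct(self) -> np.ndarray:
        return np.cumsum(self.explained_variance_pct)

    @property
    def rank(self) -> int:
        return int(self.explained_variance.size)


def pca_fit(M: np.ndarray, center: bool = True, mode: int | None = None) -> PcaModel:
    """PCA of a matrix via singular value decomposition.

    Columns are mean-centered by default (matching the tensor-centering
    philosophy of the multiway analysis); variance shares come from the
    squared singular values.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(M)):
        raise ValueError("PCA input contains non-finite values")
    if center:
        M = M - M.mean(axis=0, keepdims=True)
    if np.allclose(M, 0):
        raise ValueError("degenerate all-constant matrix has no components")
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    keep = s > s[0] * max(M.shape) * np.finfo(float).eps
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    var = s**2
    return PcaModel(
        scores=U * s,
        loadings=Vt.T,
        explained_variance=var,
        explained_variance_pct=100.0 * var / var.sum(),
        mode=mode,
    )


def pca_on_tensor(X, mode: int = 3, center: bool = True) -> PcaModel:
    """Unfold the tensor along ``mode`` (default: repetitions as
    observations) and fit PCA."""
    return pca_fit(unfold(X, mode), center=center, mode=mode)


def components_needed(model: PcaModel, threshold_pct: float = 70.0) -> int:
    """Smallest number of components reaching the cumulative-variance
    threshold; returns the full rank with a warning if unreachable."""
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold must be in (0, 100]")
    cum = model.cumulative_variance_pct
    reached = np.nonzero(cum >= threshold_pct - 1e-9)[0]
    if reached.size == 0:
        warnings.warn(
            f"cumulative variance never reaches {threshold_pct}%; "
            "returning the full rank",
            RuntimeWarning,
            stacklevel=2,
        )
        return model.rank
    return int(reached[0] + 1)
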