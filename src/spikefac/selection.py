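"""Choosing the number of PARAFAC components.

The heuristic: fit models with F = 1..F_max and keep the largest F that
(a) still adds a *significant* decrease of the residual error and (b)
explains the data *without correlated components*.

Rule (a) — the scree rule — deems the step to F significant when the
gain in explained variance, EV(F) - EV(F-1), is at least ``scree_ratio``
(default 0.1) times the largest gain of any earlier step (EV(1) counts
as the first gain); fitting one extra component into i.i.d. noise gains
far less than fitting true structure, so the gains collapse past the
true rank.  Rule (b) operationalises "correlated components" as a
maximum off-diagonal |combined Tucker congruence| above a threshold
(default 0.85): overfactoring typically produces duplicated or
degenerately cancelling components.  Both rules bind; the full trace is
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parafac import ParafacModel, als_fit, max_offdiag_congruence

__all__ = ["SelectionReport", "select_components"]

DEFAULT_CONGRUENCE_THRESHOLD = 0.85


@dataclass
class SelectionReport:
    """Trace of the component-count search."""

    candidates: tuple[int, ...]
    explained_variance_pct: tuple[float, ...]
    max_congruence: tuple[float, ...]
    chosen: int
    rationale: str
    models: dict[int, ParafacModel]
    no_admissible_above_one: bool = False

    @property
    def scree(self) -> np.ndarray:
        """First differences of explained variance over candidates."""
        return np.diff(np.asarray(self.explained_variance_pct))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "F": self.candidates,
                "explained_variance_pct": self.explained_variance_pct,
                "max_offdiag_congruence": self.max_congruence,
            }
        )
        df["chosen"] = df["F"] == self.chosen
        return df


def select_components(
    X,
    f_max: int = 6,
    congruence_threshold: float = DEFAULT_CONGRUENCE_THRESHOLD,
    scree_ratio: float = 0.1,
    n_starts: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> SelectionReport:
    """Fit F = 1..f_max and pick the largest F passing both rules.

    A candidate F passes the scree rule when its explained-variance
    gain is at least ``scree_ratio`` times the largest earlier gain,
    and the congruence rule when its best multi-start model has max
    off-diagonal |combined congruence| <= ``congruence_threshold``.
    F = 1 always passes both (no component pairs, first gain); if no
    F >= 2 passes, the report flags it and returns F = 1.
    """
    if f_max < 1:
        raise ValueError("f_max must be >= 1")
    candidates = tuple(range(1, f_max + 1))
    models: dict[int, ParafacModel] = {}
    evs, congs = [], []
    for F in candidates:
        model = als_fit(
            X, F, n_starts=n_starts, tol=tol, max_iter=max_iter, seed=seed
        )
        models[F] = model
        evs.append(model.explained_variance_pct)
        congs.append(max_offdiag_congruence(model))

    gains = np.diff([0.0] + list(evs))
    running_max = np.maximum.accumulate(gains)
    scree_ok = [True] + [
        gains[i] >= scree_ratio * running_max[i - 1]
        for i in range(1, len(candidates))
    ]
    admissible = [
        F
        for F, c, s in zip(candidates, congs, scree_ok)
        if c <= congruence_threshold and s
    ]
    chosen = max(admissible)  # F=1 always admissible
    flag = chosen == 1 and f_max > 1
    rationale = (
        f"largest F with significant residual decrease (gain >= "
        f"{scree_ratio} x largest earlier gain) and max off-diagonal "
        f"|combined congruence| <= {congruence_threshold}: F={chosen} "
        f"({evs[chosen - 1]:.2f}% variance explained)"
    )
    if flag:
        rationale += "; no F >= 2 passed both rules"
    return SelectionReport(
        candidates=candidates,
        explained_variance_pct=tuple(evs),
        max_congruence=tuple(congs),
        chosen=chosen,
        rationale=rationale,
        models=models,
        no_admissible_above_one=flag,
    )
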