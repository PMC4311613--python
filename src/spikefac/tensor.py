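"""Assemble synchrony statistics into the pair x stimulus x repetition
tensor; electrode-pair enumeration and neighbor/remote classification;
sequential centering.

The 3-way array x_ijk holds one statistic value per (electrode pair i,
stimulus j, repetition k).  On a homogeneous grid with lattice constant
d_grid, a pair is *neighboring* when its Euclidean distance is at most
sqrt(2)*d_grid (horizontal, vertical and diagonal neighbors), otherwise
*remote*; on a full 4x4 grid this yields 42 neighboring and 78 remote
pairs.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .spike_data import ElectrodeGrid

__all__ = [
    "SynchronyTensor",
    "PairClassification",
    "enumerate_pairs",
    "classify_pairs",
    "build_tensor",
    "center_tensor",
    "subset_tensor",
]


@dataclass(frozen=True)
class SynchronyTensor:
    """3-way array (pair x stimulus x repetition) with axis labels."""

    values: np.ndarray
    pairs: tuple[str, ...]
    stimuli: tuple[int, ...]
    repetitions: tuple[int, ...]
    metric: str = "kappa_sync"
    centered_modes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pairs", tuple(self.pairs))
        object.__setattr__(self, "stimuli", tuple(self.stimuli))
        object.__setattr__(self, "repetitions", tuple(self.repetitions))
        if values.ndim != 3:
            raise ValueError("tensor must be 3-way")
        if values.shape != (
            len(self.pairs),
            len(self.stimuli),
            len(self.repetitions),
        ):
            raise ValueError(
                f"shape {values.shape} does not match axis labels "
                f"({len(self.pairs)}, {len(self.stimuli)}, {len(self.repetitions)})"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("tensor contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_long_table(self) -> pd.DataFrame:
        I, J, K = self.shape
        idx = np.indices((I, J, K)).reshape(3, -1)
        return pd.DataFrame(
            {
                "pair": np.asarray(self.pairs)[idx[0]],
                "stimulus": np.asarray(self.stimuli)[idx[1]],
                "repetition": np.asarray(self.repetitions)[idx[2]],
                self.metric: self.values.ravel(),
            }
        )

    def save(self, path: str | Path) -> None:
        """Write values as a long-format TSV plus a JSON label sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.to_long_table().to_csv(
            path / "values.tsv", sep="\t", index=False, float_format="%.12g"
        )
        (path / "labels.json").write_text(
            json.dumps(
                {
                    "pairs": list(self.pairs),
                    "stimuli": list(self.stimuli),
                    "repetitions": list(self.repetitions),
                    "metric": self.metric,
                    "centered_modes": list(self.centered_modes),
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: str | Path) -> "SynchronyTensor":
        path = Path(path)
        meta = json.loads((path / "labels.json").read_text())
        table = pd.read_csv(path / "values.tsv", sep="\t", dtype={"pair": str})
        t = build_tensor(
            table,
            metric=meta["metric"],
            pair_order=meta["pairs"],
            stimulus_order=meta["stimuli"],
            repetition_order=meta["repetitions"],
        )
        return cls(
            t.values,
            t.pairs,
            t.stimuli,
            t.repetitions,
            meta["metric"],
            tuple(meta["centered_modes"]),
        )


@dataclass(frozen=True)
class PairClassification:
    """Disjoint partition of live-channel pairs by grid distance."""

    neighboring: tuple[tuple[int, int], ...]
    remote: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if set(self.neighboring) & set(self.remote):
            raise ValueError("neighboring and remote sets overlap")


def enumerate_pairs(grid: ElectrodeGrid) -> list[tuple[int, int]]:
    """All unordered pairs of live channels, (low, high), lexicographic."""
    live = grid.live_channels
    if len(live) < 2:
        raise ValueError("need at least 2 live channels to form pairs")
    return list(itertools.combinations(live, 2))


def classify_pairs(grid: ElectrodeGrid) -> PairClassification:
    """Split live pairs into neighboring (distance <= sqrt(2)*d_grid,
    i.e. including diagonal neighbors) and remote."""
    threshold = math.sqrt(2.0) * grid.grid_spacing
    near, far = [], []
    for a, b in enumerate_pairs(grid):
        # small tolerance so exact diagonal distances are not lost to fp
        if grid.distance(a, b) <= threshold * (1 + 1e-9):
            near.append((a, b))
        else:
            far.append((a, b))
    return PairClassification(tuple(near), tuple(far))


def pair_label(pair: tuple[int, int]) -> str:
    return f"{pair[0]}-{pair[1]}"


def build_tensor(
    table: pd.DataFrame,
    metric: str = "kappa_sync",
    pair_order: Sequence[str] | None = None,
    stimulus_order: Sequence[int] | None = None,
    repetition_order: Sequence[int] | None = None,
) -> SynchronyTensor:
    """Pivot a long-format metric table into the 3-way tensor.

    The table must cover the full pair x stimulus x repetition grid
    exactly once; duplicates and missing cells raise with the offending
    key named.
    """
    for col in ("pair", "stimulus", "repetition", metric):
        if col not in table.columns:
            raise ValueError(f"metric table is missing column {col!r}")
    def as_py(values):
        return tuple(
            v.item() if isinstance(v, np.generic) else v for v in values
        )

    pairs = as_py(
        pair_order if pair_order is not None else pd.unique(table["pair"])
    )
    stimuli = as_py(
        stimulus_order
        if stimulus_order is not None
        else sorted(pd.unique(table["stimulus"]))
    )
    reps = as_py(
        repetition_order
        if repetition_order is not None
        else sorted(pd.unique(table["repetition"]))
    )
    p_idx = {p: i for i, p in enumerate(pairs)}
    s_idx = {s: j for j, s in enumerate(stimuli)}
    r_idx = {r: k for k, r in enumerate(reps)}

    values = np.full((len(pairs), len(stimuli), len(reps)), np.nan)
    for row in table.itertuples():
        key = (row.pair, row.stimulus, row.repetition)
        try:
            i, j, k = p_idx[key[0]], s_idx[key[1]], r_idx[key[2]]
        except KeyError:
            raise ValueError(f"table row with unknown label {key}") from None
        if not np.isnan(values[i, j, k]):
            raise ValueError(f"duplicate cell for {key}")
        values[i, j, k] = getattr(row, metric)
    if np.isnan(values).any():
        i, j, k = np.argwhere(np.isnan(values))[0]
        raise ValueError(
            f"missing cell (pair={pairs[i]}, stimulus={stimuli[j]}, "
            f"repetition={reps[k]})"
        )
    return SynchronyTensor(values, pairs, stimuli, reps, metric)


def center_tensor(
    X: SynchronyTensor, modes: Sequence[int] = (1, 2, 3)
) -> SynchronyTensor:
    """Sequential single-mode centering in the given order.

    For each mode in turn, the mean across that mode is subtracted from
    every fiber of the *result of the previous centering*.  Modes are
    1-based (1 = pair, 2 = stimulus, 3 = repetition).  Note that
    sequential centering only guarantees zero fiber means for the mode
    centered last.
    """
    modes = tuple(modes)
    if len(set(modes)) != len(modes) or not set(modes) <= {1, 2, 3}:
        raise ValueError("modes must be a subset of {1,2,3} without repeats")
    values = X.values.copy()
    for m in modes:
        if values.shape[m - 1] == 1:
            raise ValueError(f"cannot center along degenerate mode {m}")
        values = values - values.mean(axis=m - 1, keepdims=True)
    return SynchronyTensor(
        values,
        X.pairs,
        X.stimuli,
        X.repetitions,
        X.metric,
        X.centered_modes + modes,
    )


def subset_tensor(
    X: SynchronyTensor, pairs: Sequence[tuple[int, int] | str]
) -> SynchronyTensor:
    """Slice the tensor to a subset of electrode pairs (labels kept)."""
    labels = [p if isinstance(p, str) else pair_label(p) for p in pairs]
    index = {p: i for i, p in enumerate(X.pairs)}
    unknown = [p for p in labels if p not in index]
    if unknown:
        raise ValueError(f"unknown pair labels: {unknown}")
    rows = [index[p] for p in labels]
    return SynchronyTensor(
        X.values[rows],
        tuple(labels),
        X.stimuli,
        X.repetitions,
        X.metric,
        X.centered_modes,
    )
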