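"""Domain containers for multi-electrode spike recordings.

The pipeline starts from spike *event times* (seconds), organised by
(channel, stimulus, repetition).  Raw-signal filtering and threshold
detection are upstream of this package.  Spike trains are converted to
binned vectors (default 2 ms bins) before any correlation analysis.

A :class:`SpikeDataset` is stored on disk as a directory of three
tab-separated tables:

``grid.tsv``
    columns ``channel``, ``x``, ``y``, ``dead`` — electrode positions in
    µm and a 0/1 dead flag.
``spikes.tsv``
    columns ``channel``, ``stimulus``, ``repetition``, ``time_s`` — one
    spike event per row.
``meta.tsv``
    key/value rows: ``duration_s``, ``grid_spacing_um``,
    ``stimulus:<id>`` (catalogue entries) and ``phase:<repetition>``
    (phase label per repetition: warm / deactivation / rewarm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ElectrodeGrid",
    "SpikeTrain",
    "BinnedTrain",
    "SpikeDataset",
    "bin_spike_train",
    "read_dataset",
    "write_dataset",
]

PHASES = ("warm", "deactivation", "rewarm")


@dataclass(frozen=True)
class ElectrodeGrid:
    """Electrode positions on a (possibly incomplete) planar grid.

    Parameters
    ----------
    positions
        Mapping channel id -> (x, y) coordinate in µm.
    grid_spacing
        Lattice constant d_grid in µm (> 0).
    dead_channels
        Channels present in the array but excluded from analysis.
    """

    positions: dict[int, tuple[float, float]]
    grid_spacing: float
    dead_channels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        coords = list(self.positions.values())
        if len(set(coords)) != len(coords):
            raise ValueError("electrode positions must be distinct")
        object.__setattr__(self, "dead_channels", frozenset(self.dead_channels))
        unknown = self.dead_channels - set(self.positions)
        if unknown:
            raise ValueError(f"dead channels not in grid: {sorted(unknown)}")

    @property
    def channels(self) -> list[int]:
        return sorted(self.positions)

    @property
    def live_channels(self) -> list[int]:
        return [c for c in self.channels if c not in self.dead_channels]

    def distance(self, a: int, b: int) -> float:
        (xa, ya), (xb, yb) = self.positions[a], self.positions[b]
        return math.hypot(xa - xb, ya - yb)

    @classmethod
    def regular(
        cls,
        n_rows: int,
        n_cols: int,
        spacing: float,
        dead_channels: Iterable[int] = (),
    ) -> "ElectrodeGrid":
        """Homogeneous n_rows x n_cols lattice; channel = row*n_cols + col."""
        positions = {
            r * n_cols + c: (c * spacing, r * spacing)
            for r in range(n_rows)
            for c in range(n_cols)
        }
        return cls(positions, spacing, frozenset(dead_channels))


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike event times (s) of one channel in one trial."""

    times: np.ndarray
    duration: float
    channel: int
    stimulus: int
    repetition: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size:
            if np.any(np.diff(times) < 0):
                raise ValueError("spike times must be sorted ascending")
            if times[0] < 0 or times[-1] >= self.duration:
                raise ValueError(
                    f"spike times must lie in [0, {self.duration}) s"
                )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class BinnedTrain:
    """Spike train discretised into bins of width ``bin_width`` seconds.

    Bin k covers the half-open interval [k*Δ, (k+1)*Δ).  In ``binary``
    mode multiple events in one bin clip to 1.
    """

    values: np.ndarray
    bin_width: float
    mode: Literal["binary", "count"] = "binary"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        if self.bin_width <= 0:
            raise ValueError("bin width must be positive")
        if self.mode == "binary" and values.size and values.max(initial=0) > 1:
            raise ValueError("binary train contains values > 1")

    def __len__(self) -> int:
        return int(self.values.size)


def bin_spike_train(
    train: SpikeTrain,
    bin_width: float = 0.002,
    mode: Literal["binary", "count"] = "binary",
) -> BinnedTrain:
    """Discretise a spike train into bins of width ``bin_width``.

    The train length is ``ceil(duration / bin_width)`` bins; bin k covers
    [kΔ, (k+1)Δ).  ``count`` mode conserves the number of events,
    ``binary`` clips each bin to {0, 1}.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    n_bins = math.ceil(train.duration / bin_width)
    idx = np.floor(train.times / bin_width).astype(int)
    # events exactly at duration are excluded by SpikeTrain's invariant;
    # floating point may still push an index to n_bins - guard anyway
    if idx.size and (idx.min() < 0 or idx.max() >= n_bins):
        raise ValueError("spike time outside [0, duration)")
    counts = np.bincount(idx, minlength=n_bins)
    if mode == "binary":
        values = (counts > 0).astype(np.int8)
    elif mode == "count":
        values = counts
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return BinnedTrain(values=values, bin_width=bin_width, mode=mode)


@dataclass
class SpikeDataset:
    """All spike trains of one experiment plus geometry and schedule."""

    grid: ElectrodeGrid
    trains: dict[tuple[int, int, int], SpikeTrain]
    phase_labels: dict[int, str]
    stimuli: dict[int, str]
    duration: float

    def __post_init__(self) -> None:
        live = set(self.grid.live_channels)
        for (ch, stim, rep), train in self.trains.items():
            if ch not in live:
                raise ValueError(
                    f"train recorded on dead or unknown channel {ch}"
                )
            if stim not in self.stimuli:
                raise ValueError(f"train references unknown stimulus {stim}")
            if rep not in self.phase_labels:
                raise ValueError(
                    f"train references repetition {rep} with no phase label"
                )
            if not math.isclose(train.duration, self.duration):
                raise ValueError(
                    f"train {(ch, stim, rep)} duration {train.duration} "
                    f"!= dataset duration {self.duration}"
                )
        bad = set(self.phase_labels.values()) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")

    @property
    def repetitions(self) -> list[int]:
        return sorted(self.phase_labels)

    @property
    def stimulus_ids(self) -> list[int]:
        return sorted(self.stimuli)

    def train(self, channel: int, stimulus: int, repetition: int) -> SpikeTrain:
        key = (channel, stimulus, repetition)
        if key not in self.trains:
            return SpikeTrain(
                np.empty(0), self.duration, channel, stimulus, repetition
            )
        return self.trains[key]


def write_dataset(dataset: SpikeDataset, path: str | Path) -> None:
    """Write a dataset to a directory of TSV tables (see module docstring)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    grid_rows = [
        {
            "channel": ch,
            "x": dataset.grid.positions[ch][0],
            "y": dataset.grid.positions[ch][1],
            "dead": int(ch in dataset.grid.dead_channels),
        }
        for ch in dataset.grid.channels
    ]
    pd.DataFrame(grid_rows).to_csv(path / "grid.tsv", sep="\t", index=False)

    spike_rows = []
    for (ch, stim, rep), train in sorted(dataset.trains.items()):
        for t in train.times:
            spike_rows.append((ch, stim, rep, t))
    pd.DataFrame(
        spike_rows, columns=["channel", "stimulus", "repetition", "time_s"]
    ).to_csv(path / "spikes.tsv", sep="\t", index=False, float_format="%.9f")

    meta_rows = [("duration_s", repr(dataset.duration)),
                 ("grid_spacing_um", repr(dataset.grid.grid_spacing))]
    meta_rows += [(f"stimulus:{k}", v) for k, v in sorted(dataset.stimuli.items())]
    meta_rows += [
        (f"phase:{k}", v) for k, v in sorted(dataset.phase_labels.items())
    ]
    pd.DataFrame(meta_rows, columns=["key", "value"]).to_csv(
        path / "meta.tsv", sep="\t", index=False
    )


def read_dataset(path: str | Path) -> SpikeDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    for name in ("grid.tsv", "spikes.tsv", "meta.tsv"):
        if not (path / name).exists():
            raise FileNotFoundError(f"dataset container missing table {name}")

    grid_df = pd.read_csv(path / "grid.tsv", sep="\t")
    _require_columns(grid_df, ("channel", "x", "y", "dead"), "grid.tsv")
    meta_df = pd.read_csv(path / "meta.tsv", sep="\t", dtype=str)
    _require_columns(meta_df, ("key", "value"), "meta.tsv")
    meta: Mapping[str, str] = dict(zip(meta_df["key"], meta_df["value"]))

    if "duration_s" not in meta:
        raise ValueError("meta.tsv is missing the duration_s row")
    if "grid_spacing_um" not in meta:
        raise ValueError("meta.tsv is missing the grid_spacing_um row")
    duration = float(meta["duration_s"])

    stimuli = {
        int(k.split(":", 1)[1]): v
        for k, v in meta.items()
        if k.startswith("stimulus:")
    }
    phase_labels = {
        int(k.split(":", 1)[1]): v
        for k, v in meta.items()
        if k.startswith("phase:")
    }
    if not phase_labels:
        raise ValueError("meta.tsv contains no phase:<repetition> rows")
    if not stimuli:
        raise ValueError("meta.tsv contains no stimulus:<id> rows")

    grid = ElectrodeGrid(
        positions={
            int(r.channel): (float(r.x), float(r.y))
            for r in grid_df.itertuples()
        },
        grid_spacing=float(meta["grid_spacing_um"]),
        dead_channels=frozenset(
            int(r.channel) for r in grid_df.itertuples() if int(r.dead)
        ),
    )

    spikes_df = pd.read_csv(path / "spikes.tsv", sep="\t")
    _require_columns(
        spikes_df, ("channel", "stimulus", "repetition", "time_s"), "spikes.tsv"
    )
    trains: dict[tuple[int, int, int], SpikeTrain] = {}
    for (ch, stim, rep), group in spikes_df.groupby(
        ["channel", "stimulus", "repetition"], sort=True
    ):
        key = (int(ch), int(stim), int(rep))
        trains[key] = SpikeTrain(
            np.sort(group["time_s"].to_numpy(float)), duration, *key
        )
    return SpikeDataset(grid, trains, phase_labels, stimuli, duration)


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{table} is missing columns {missing}")
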