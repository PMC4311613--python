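"""Raw, jitter and normalized cross-correlograms of binned spike trains.

The raw correlogram of two binned trains x, y is

    lambda_raw(tau) = sum_t x(t) * y(t + tau),        tau = -L..+L bins,

with out-of-range products contributing zero.  Rate-driven chance
coincidences are removed by jitter correction: both trains are convolved
with a homogeneous "jitter kernel" of width T_jitter (equal taps summing
to one, equivalent to uniformly re-drawing each spike time within
T_jitter), the correlogram of the convolved trains is computed and
subtracted:

    lambda(tau) = lambda_raw(tau) - lambda_jitter(tau).

The convolution acts at the binned resolution (a 3-tap kernel for
T_jitter = 6 ms at 2 ms bins); edges are zero-padded and the convolved
train keeps the input length ("same" convolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import signal

from .spike_data import BinnedTrain

__all__ = [
    "Correlogram",
    "raw_correlogram",
    "jitter_kernel",
    "jitter_correlogram",
    "normalized_correlogram",
]

DEFAULT_MAX_LAG = 50          # bins; +-100 ms at 2 ms resolution
DEFAULT_T_JITTER = 0.006      # s


@dataclass(frozen=True)
class Correlogram:
    """Lag-indexed correlogram values with provenance.

    ``lags`` runs over -L..+L bins with lag 0 at the centre index L;
    ``values[i]`` is the correlogram at ``lags[i]``.
    """

    lags: np.ndarray
    values: np.ndarray
    bin_width: float
    kind: Literal["raw", "jitter", "normalized"]
    pair: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        if lags.size != values.size:
            raise ValueError("lags and values must have equal length")
        L = (lags.size - 1) // 2
        if lags.size != 2 * L + 1 or lags[L] != 0:
            raise ValueError("lags must be symmetric -L..+L with 0 centred")

    @property
    def max_lag(self) -> int:
        return (self.lags.size - 1) // 2

    def at(self, lag: int) -> float:
        """Value at an integer lag in bins."""
        return float(self.values[lag + self.max_lag])

    def to_tsv(self, path: str | Path, t_jitter: float | None = None) -> None:
        """Export as a lag/value table with a metadata header block."""
        lines = [f"# kind\t{self.kind}", f"# bin_width_s\t{self.bin_width!r}"]
        if t_jitter is not None:
            lines.append(f"# t_jitter_s\t{t_jitter!r}")
        if self.pair is not None:
            lines.append(f"# pair\t{self.pair[0]},{self.pair[1]}")
        lines.append("lag_bins\tvalue")
        lines += [f"{l}\t{v!r}" for l, v in zip(self.lags, self.values)]
        Path(path).write_text("\n".join(lines) + "\n")


def _check_pair(x: BinnedTrain, y: BinnedTrain, max_lag: int) -> None:
    if len(x) != len(y):
        raise ValueError(f"train lengths differ: {len(x)} vs {len(y)}")
    if not np.isclose(x.bin_width, y.bin_width):
        raise ValueError("bin widths differ")
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")


def _xcorr(xv: np.ndarray, yv: np.ndarray, max_lag: int) -> np.ndarray:
    """sum_t x(t) y(t+tau) for tau = -L..L, zero outside the data."""
    n = xv.size
    # full cross-correlation; index n-1+tau holds sum_t x(t) y(t+tau)
    full = signal.correlate(yv.astype(float), xv.astype(float), mode="full")
    centre = n - 1
    L = max_lag
    out = np.zeros(2 * L + 1)
    lo, hi = max(-L, -(n - 1)), min(L, n - 1)
    out[lo + L : hi + L + 1] = full[centre + lo : centre + hi + 1]
    return out


def raw_correlogram(
    x: BinnedTrain,
    y: BinnedTrain,
    max_lag: int = DEFAULT_MAX_LAG,
    pair: tuple[int, int] | None = None,
) -> Correlogram:
    """Raw cross-correlogram sum_t x(t) y(t+tau) over tau = -L..+L bins."""
    _check_pair(x, y, max_lag)
    values = _xcorr(np.asarray(x.values), np.asarray(y.values), max_lag)
    return Correlogram(
        np.arange(-max_lag, max_lag + 1), values, x.bin_width, "raw", pair
    )


def jitter_kernel(t_jitter: float, bin_width: float) -> np.ndarray:
    """Homogeneous kernel of width t_jitter: equal taps summing to 1."""
    if t_jitter < bin_width:
        raise ValueError("t_jitter must be at least one bin width")
    n_taps = int(round(t_jitter / bin_width))
    return np.full(n_taps, 1.0 / n_taps)


def jitter_correlogram(
    x: BinnedTrain,
    y: BinnedTrain,
    max_lag: int = DEFAULT_MAX_LAG,
    t_jitter: float = DEFAULT_T_JITTER,
    pair: tuple[int, int] | None = None,
) -> Correlogram:
    """Correlogram of the two jitter-kernel-convolved trains.

    Both trains are convolved with the homogeneous kernel ("same"
    length, zero-padded edges) before correlating; this equals the
    expectation of the raw correlogram under uniform re-jittering of
    every spike within t_jitter.
    """
    _check_pair(x, y, max_lag)
    kernel = jitter_kernel(t_jitter, x.bin_width)
    xs = np.convolve(np.asarray(x.values, float), kernel, mode="same")
    ys = np.convolve(np.asarray(y.values, float), kernel, mode="same")
    values = _xcorr(xs, ys, max_lag)
    return Correlogram(
        np.arange(-max_lag, max_lag + 1), values, x.bin_width, "jitter", pair
    )


def normalized_correlogram(
    x: BinnedTrain,
    y: BinnedTrain,
    max_lag: int = DEFAULT_MAX_LAG,
    t_jitter: float = DEFAULT_T_JITTER,
    pair: tuple[int, int] | None = None,
) -> Correlogram:
    """Jitter-corrected correlogram: raw minus jitter, elementwise."""
    raw = raw_correlogram(x, y, max_lag, pair)
    jit = jitter_correlogram(x, y, max_lag, t_jitter, pair)
    return Correlogram(
        raw.lags, raw.values - jit.values, x.bin_width, "normalized", pair
    )
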