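"""Synthetic data with known ground truth.

Two generators:

* :func:`simulate_tensor` draws a tensor with exact trilinear structure
  X = sum_f a_f o b_f o c_f + Gaussian noise, returning the planted
  loadings — the fixture for decomposition, selection and validation
  tests.
* :func:`simulate_experiment` emulates the multi-electrode deactivation
  experiment the analysis was designed for: a 4x4 electrode grid
  (500 µm spacing, one dead channel, 15 live), 8 stimulus conditions
  (4 grating orientations x 2 motion directions), 8 s trials, and 63
  repetitions per stimulus from a 3+3+3-cycle schedule with 7
  repetitions per cycle — repetitions 1-21 warm, 22-42 with feedback
  deactivated, 43-63 after rewarming.

Pairwise synchrony is injected by a shared-event ("mother process")
mechanism: cell assemblies (channel groups) receive common Poisson
events, inserted into each member channel with independent Gaussian
timing jitter.  The mother-process rate factorises as
base rate x stimulus tuning x phase multiplier, which is exactly the
trilinear (pair x stimulus x repetition-phase) structure the PARAFAC
model assumes, so planted assemblies are recoverable as components.
Optional common gamma-band (default 40 Hz) sinusoidal rate modulation
of a channel group creates oscillatory synchrony for kappa_oscsync.

The real recordings' within-trial rate nonstationarity (gray / static /
moving grating epochs) can be emulated with per-epoch rate factors; by
default rates are homogeneous.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .parafac import _normalize
from .spike_data import ElectrodeGrid, SpikeDataset, SpikeTrain
from .tensor import SynchronyTensor, pair_label

__all__ = [
    "TensorSimConfig",
    "Assembly",
    "ExperimentSimConfig",
    "simulate_tensor",
    "simulate_experiment",
    "default_assemblies",
]


# ---------------------------------------------------------------------------
# trilinear tensor fixture


@dataclass(frozen=True)
class TensorSimConfig:
    """Configuration of the planted-trilinear-tensor generator.

    shape : (I, J, K) tensor dimensions.
    rank : number of planted components R >= 1.
    noise_sd : SD of i.i.d. Gaussian noise relative to the SD of the
        noiseless signal (0.1 = 10% noise).
    max_congruence : maximum allowed pairwise |congruence| between
        planted loading columns in any single mode (re-drawn until
        satisfied) — keeps components well separated.
    loading_dist : "uniform" draws loadings in [0, 1); "normal" draws
        standard normal loadings.
    """

    shape: tuple[int, int, int] = (20, 8, 30)
    rank: int = 3
    noise_sd: float = 0.05
    max_congruence: float = 0.8
    loading_dist: str = "uniform"
    max_retries: int = 200

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_loadings(
    n: int, rank: int, rng: np.random.Generator, cfg: TensorSimConfig
) -> np.ndarray:
    for _ in range(cfg.max_retries):
        if cfg.loading_dist == "uniform":
            M = rng.uniform(size=(n, rank))
        elif cfg.loading_dist == "normal":
            M = rng.normal(size=(n, rank))
        else:
            raise ValueError(f"unknown loading_dist {cfg.loading_dist!r}")
        if rank == 1:
            return M
        norms = np.linalg.norm(M, axis=0)
        if np.any(norms == 0):
            continue
        G = (M.T @ M) / np.outer(norms, norms)
        off = np.abs(G[~np.eye(rank, dtype=bool)])
        if off.max() <= cfg.max_congruence:
            return M
    raise RuntimeError(
        f"could not draw {rank} loading columns with pairwise congruence "
        f"<= {cfg.max_congruence} in {cfg.max_retries} tries"
    )


def simulate_tensor(
    cfg: TensorSimConfig = TensorSimConfig(), seed: int | None = None
):
    """Draw X = sum_f a_f o b_f o c_f + eps with known loadings.

    Returns ``(tensor, (A, B, C))`` where the loadings are in the
    package normalization (unit-norm B/C columns, sign-fixed, ordered
    by contribution) so they compare directly with fitted models.
    """
    rng = np.random.default_rng(seed)
    I, J, K = cfg.shape
    A = _draw_loadings(I, cfg.rank, rng, cfg)
    B = _draw_loadings(J, cfg.rank, rng, cfg)
    C = _draw_loadings(K, cfg.rank, rng, cfg)
    signal = np.einsum("if,jf,kf->ijk", A, B, C)
    noise = rng.normal(size=cfg.shape) * (cfg.noise_sd * signal.std())
    A, B, C = _normalize(A, B, C)
    tensor = SynchronyTensor(
        signal + noise,
        pairs=tuple(f"p{i}" for i in range(I)),
        stimuli=tuple(range(J)),
        repetitions=tuple(range(1, K + 1)),
        metric="synthetic",
    )
    return tensor, (A, B, C)


# ---------------------------------------------------------------------------
# spiking experiment emulation


@dataclass(frozen=True)
class Assembly:
    """A channel group sharing injected coincident events.

    channels : live channel ids receiving the common events.
    rate_hz : mother-process base rate (events/s) before tuning.
    stimulus_weights : per-stimulus multiplicative tuning (length = the
        number of stimuli).
    phase_multipliers : (warm, deactivation, rewarm) rate factors —
    the deactivation sensitivity of this assembly's synchrony.
    """

    channels: tuple[int, ...]
    rate_hz: float
    stimulus_weights: tuple[float, ...]
    phase_multipliers: tuple[float, float, float] = (1.0, 0.3, 1.0)

    def __post_init__(self) -> None:
        if self.rate_hz < 0 or min(self.phase_multipliers) < 0:
            raise ValueError("rates and multipliers must be >= 0")
        if min(self.stimulus_weights) < 0:
            raise ValueError("stimulus weights must be >= 0")


def _gaussian_tuning(n_stimuli: int, peak: int, width: float = 1.0,
                     floor: float = 0.05) -> tuple[float, ...]:
    """Orientation-tuning-like profile over stimulus ids, circular."""
    w = []
    for s in range(n_stimuli):
        d = min(abs(s - peak), n_stimuli - abs(s - peak))
        w.append(floor + (1 - floor) * math.exp(-0.5 * (d / width) ** 2))
    return tuple(w)


def default_assemblies(n_stimuli: int = 8) -> tuple[Assembly, ...]:
    """Three planted assemblies with distinct spatial footprints,
    stimulus tuning, and deactivation sensitivity (rank-3 ground
    truth).  Channel ids refer to the default 4x4 grid with channel 5
    dead.

    Shared-event rates are strong relative to the background (a
    majority of member-channel multi-unit spikes are common events):
    the emulation targets the regime of the recorded sessions, where
    pairwise synchrony was prominent enough that a handful of trilinear
    components explained the bulk of the tensor's variance.  Sharp
    orientation tuning (width 0.8 stimulus steps) keeps most of the
    stimulus-mode signal in the interaction terms that survive
    centering.
    """
    return (
        Assembly((0, 1, 4, 8, 9), 25.0, _gaussian_tuning(n_stimuli, 0, 0.8, 0.02),
                 (1.0, 0.2, 1.0)),
        Assembly((10, 11, 12, 14, 15), 25.0,
                 _gaussian_tuning(n_stimuli, 4, 0.8, 0.02), (1.0, 0.4, 0.8)),
        Assembly((2, 3, 6, 7), 20.0, _gaussian_tuning(n_stimuli, 6, 0.8, 0.02),
                 (0.6, 0.6, 1.3)),
    )


@dataclass(frozen=True)
class ExperimentSimConfig:
    """Study-condition parameters of the emulated experiment.

    Defaults reproduce the recorded experiment's geometry and schedule:
    4x4 grid at 500 µm with one dead channel; 4 orientations x 2
    directions = 8 stimuli; 3 cycles x 7 repetitions per phase (warm,
    deactivation, rewarm) = 63 repetitions per stimulus; 8 s trials
    (2 s gray + 2 s static + 4 s moving grating).
    """

    n_rows: int = 4
    n_cols: int = 4
    grid_spacing: float = 500.0
    dead_channels: tuple[int, ...] = (5,)
    n_orientations: int = 4
    n_directions: int = 2
    cycles_per_phase: int = 3
    reps_per_cycle: int = 7
    t_gray: float = 2.0
    t_static: float = 2.0
    t_moving: float = 4.0
    background_rate_hz: float = 10.0
    epoch_rate_factors: tuple[float, float, float] | None = None
    assemblies: tuple[Assembly, ...] | None = None
    jitter_sd: float = 0.001
    osc_freq_hz: float = 40.0
    osc_depth: float = 0.0
    osc_channels: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.background_rate_hz < 0:
            raise ValueError("background rate must be >= 0")
        if not 0 <= self.osc_depth <= 1:
            raise ValueError("osc_depth must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")

    @property
    def n_stimuli(self) -> int:
        return self.n_orientations * self.n_directions

    @property
    def n_repetitions(self) -> int:
        return 3 * self.cycles_per_phase * self.reps_per_cycle

    @property
    def duration(self) -> float:
        return self.t_gray + self.t_static + self.t_moving

    def phase_of(self, repetition: int) -> int:
        """0 = warm, 1 = deactivation, 2 = rewarm (repetition 1-based)."""
        per_phase = self.cycles_per_phase * self.reps_per_cycle
        return min((repetition - 1) // per_phase, 2)


_PHASE_NAMES = ("warm", "deactivation", "rewarm")


def _poisson_times(rate: float, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, size=n))


def _thin_oscillation(times: np.ndarray, depth: float, freq: float,
                      phase: float, rng: np.random.Generator) -> np.ndarray:
    """Thin a homogeneous train to rate proportional to
    1 + depth*sin(2*pi*freq*t + phase)."""
    if depth == 0 or times.size == 0:
        return times
    accept = rng.uniform(0, 1 + depth, size=times.size) <= (
        1 + depth * np.sin(2 * np.pi * freq * times + phase)
    )
    return times[accept]


def simulate_experiment(
    cfg: ExperimentSimConfig = ExperimentSimConfig(), seed: int | None = None
) -> SpikeDataset:
    """Generate a full synthetic spiking session.

    Per channel and trial, homogeneous Poisson background spikes
    (optionally epoch-rate-stepped and/or gamma-modulated by thinning,
    with a shared random oscillation phase per trial within the
    designated channel group).  Per assembly, stimulus and trial, a
    Poisson mother train at rate
    ``rate_hz * stimulus_weights[s] * phase_multipliers[phase]`` is
    inserted into every member channel with independent N(0, jitter_sd)
    timing jitter (events jittered outside the trial are dropped).
    """
    rng = np.random.default_rng(seed)
    grid = ElectrodeGrid.regular(
        cfg.n_rows, cfg.n_cols, cfg.grid_spacing, cfg.dead_channels
    )
    live = grid.live_channels
    assemblies = (
        cfg.assemblies
        if cfg.assemblies is not None
        else default_assemblies(cfg.n_stimuli)
    )
    for asm in assemblies:
        if len(asm.stimulus_weights) != cfg.n_stimuli:
            raise ValueError(
                "assembly stimulus_weights length must equal n_stimuli"
            )
        if not set(asm.channels) <= set(live):
            raise ValueError(
                f"assembly channels {asm.channels} not all live on the grid"
            )
        peak_rate = asm.rate_hz * max(asm.stimulus_weights) * max(
            asm.phase_multipliers
        )
        if peak_rate > 3.0 * cfg.background_rate_hz:
            import warnings

            warnings.warn(
                f"injection rate {peak_rate:.1f} Hz exceeds 3x the "
                f"background rate {cfg.background_rate_hz:.1f} Hz; over 75% "
                "of member-channel spikes would be shared events",
                RuntimeWarning,
                stacklevel=2,
            )

    duration = cfg.duration
    osc_set = set(cfg.osc_channels or live)
    stimuli = {
        o * cfg.n_directions + d: f"ori{o * 180 // cfg.n_orientations}_dir{d}"
        for o in range(cfg.n_orientations)
        for d in range(cfg.n_directions)
    }
    phase_labels = {
        rep: _PHASE_NAMES[cfg.phase_of(rep)]
        for rep in range(1, cfg.n_repetitions + 1)
    }

    edges = np.array([0.0, cfg.t_gray, cfg.t_gray + cfg.t_static, duration])
    factors = cfg.epoch_rate_factors

    trains: dict[tuple[int, int, int], SpikeTrain] = {}
    for stim in stimuli:
        for rep in range(1, cfg.n_repetitions + 1):
            osc_phase = rng.uniform(0, 2 * np.pi)
            events: dict[int, list[np.ndarray]] = {ch: [] for ch in live}
            for ch in live:
                if factors is None:
                    bg = _poisson_times(cfg.background_rate_hz, duration, rng)
                else:
                    parts = []
                    for e, f in enumerate(factors):
                        seg = _poisson_times(
                            cfg.background_rate_hz * f,
                            edges[e + 1] - edges[e],
                            rng,
                        )
                        parts.append(seg + edges[e])
                    bg = np.concatenate(parts)
                if cfg.osc_depth > 0 and ch in osc_set:
                    bg = _thin_oscillation(
                        bg, cfg.osc_depth, cfg.osc_freq_hz, osc_phase, rng
                    )
                events[ch].append(bg)
            phase = cfg.phase_of(rep)
            for asm in assemblies:
                rate = (
                    asm.rate_hz
                    * asm.stimulus_weights[stim]
                    * asm.phase_multipliers[phase]
                )
                mother = _poisson_times(rate, duration, rng)
                for ch in asm.channels:
                    jittered = mother + rng.normal(
                        0, cfg.jitter_sd, size=mother.size
                    )
                    jittered = jittered[(jittered >= 0) & (jittered < duration)]
                    events[ch].append(jittered)
            for ch in live:
                t = np.sort(np.concatenate(events[ch]))
                # merge coincident duplicates produced by jitter clipping
                trains[(ch, stim, rep)] = SpikeTrain(
                    t, duration, ch, stim, rep
                )
    return SpikeDataset(grid, trains, phase_labels, stimuli, duration)


def planted_pair_loadings(
    cfg: ExperimentSimConfig, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Ground-truth pair-mode pattern: for each assembly (column), 1 on
    pairs whose two channels are both members, else 0."""
    assemblies = (
        cfg.assemblies
        if cfg.assemblies is not None
        else default_assemblies(cfg.n_stimuli)
    )
    out = np.zeros((len(pairs), len(assemblies)))
    for f, asm in enumerate(assemblies):
        members = set(asm.channels)
        for i, (a, b) in enumerate(pairs):
            if a in members and b in members:
                out[i, f] = 1.0
    return out


def planted_truth(cfg: ExperimentSimConfig) -> dict:
    """JSON-serialisable sidecar describing the planted structure."""
    assemblies = (
        cfg.assemblies
        if cfg.assemblies is not None
        else default_assemblies(cfg.n_stimuli)
    )
    return {
        "assemblies": [
            {
                "channels": list(a.channels),
                "rate_hz": a.rate_hz,
                "stimulus_weights": list(a.stimulus_weights),
                "phase_multipliers": list(a.phase_multipliers),
                "pairs": [
                    pair_label(p)
                    for p in itertools.combinations(sorted(a.channels), 2)
                ],
            }
            for a in assemblies
        ],
        "jitter_sd": cfg.jitter_sd,
        "osc_freq_hz": cfg.osc_freq_hz,
        "osc_depth": cfg.osc_depth,
    }
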