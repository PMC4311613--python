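"""The two scalar synchrony statistics of a normalized correlogram.

kappa_sync is the largest non-negative correlogram peak within +-5 ms
of zero lag; kappa_oscsync is the share of the correlogram's spectral
power inside a frequency band (here low gamma, 30-50 Hz).
"""

import numpy as np

import spikefac as sf

rng = np.random.default_rng(1)
bw, n = 0.002, 30000

# pair 1: shared coincident events only
shared = rng.random(n) < 4.0 * bw
x1 = sf.BinnedTrain(((rng.random(n) < 15.0 * bw) | shared).astype(int), bw)
y1 = sf.BinnedTrain(((rng.random(n) < 15.0 * bw) | shared).astype(int), bw)

# pair 2: common 40 Hz rate modulation (gamma), no extra coincidences
t = np.arange(n) * bw
gamma = 0.5 * (1 + 0.9 * np.sin(2 * np.pi * 40.0 * t))
x2 = sf.BinnedTrain((rng.random(n) < 30.0 * bw * gamma).astype(int), bw)
y2 = sf.BinnedTrain((rng.random(n) < 30.0 * bw * gamma).astype(int), bw)

cfg = sf.MetricConfig(t_sync=0.005, f_min=30.0, f_max=50.0)
for name, (x, y) in {
    "coincidence pair": (x1, y1),
    "gamma-modulated pair": (x2, y2),
}.items():
    c = sf.normalized_correlogram(x, y, max_lag=50)
    print(
        f"{name:22s} kappa_sync = {sf.kappa_sync(c, cfg):6.2f}   "
        f"kappa_oscsync(30-50 Hz) = {sf.kappa_oscsync(c, cfg):.3f}"
    )

print()
print(
    "The coincidence pair scores high on kappa_sync (a sharp zero-lag "
    "peak) but low on band power; the gamma pair shows the opposite "
    "signature - an oscillatory correlogram whose power concentrates "
    "in the 30-50 Hz band."
)
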