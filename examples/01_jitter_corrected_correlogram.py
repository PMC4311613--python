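"""Raw vs jitter-corrected cross-correlograms.

Two Poisson spike trains share injected coincident events on top of
independent background firing.  The raw correlogram mixes rate-driven
chance coincidences with genuine synchrony; subtracting the
jitter-kernel correlogram (spikes locally uniformised within 6 ms)
leaves only the excess synchrony near zero lag.
"""

import numpy as np

import spikefac as sf

rng = np.random.default_rng(0)
duration, bw = 60.0, 0.002
n = int(duration / bw)

# shared events at 5 Hz, independent background at 20 Hz
shared = rng.random(n) < 5.0 * bw
x = sf.BinnedTrain(((rng.random(n) < 20.0 * bw) | shared).astype(int), bw)
y = sf.BinnedTrain(((rng.random(n) < 20.0 * bw) | shared).astype(int), bw)

raw = sf.raw_correlogram(x, y, max_lag=5)
norm = sf.normalized_correlogram(x, y, max_lag=5, t_jitter=0.006)

print("lag (bins):      ", "  ".join(f"{l:+d}" for l in raw.lags))
print("raw counts:      ", "  ".join(f"{v:.0f}" for v in raw.values))
print("jitter-corrected:", "  ".join(f"{v:+.1f}" for v in norm.values))
print()
print(
    f"The raw correlogram sits near its chance level "
    f"(~{raw.values.mean():.0f} coincidences per lag) everywhere except "
    f"zero lag; jitter correction removes the chance level, leaving the "
    f"zero-lag excess of {norm.at(0):.1f} coincidences - the injected "
    "synchrony - flanked by the small negative dips the kernel "
    "subtraction produces around a peak sharper than the jitter window."
)
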