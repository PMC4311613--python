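# Methods

This note documents the models, the numerical conventions, the choices
made where a convention was genuinely open, what the synthetic data
emulate, and the package's limitations.  It states no empirical result
that the tests or `scripts/acceptance.py` do not themselves compute.

## Pipeline model

The pipeline estimates how pairwise spike synchrony depends on
electrode pair, stimulus and trial, in four stages: binned spike
trains → jitter-corrected cross-correlograms → scalar synchrony
statistics → a 3-way tensor decomposed by PARAFAC.

### Binning

Spike event times (seconds) are discretised into bins of width
Δ = 2 ms (configurable).  Bins are half-open, 0-based:
bin k covers [kΔ, (k+1)Δ).  Binary mode clips multiple events per bin
to 1; count mode conserves event counts exactly.  The pipeline ingests
event times, not raw voltage — threshold detection of multi-unit
activity is upstream and out of scope, which keeps the package
recording-hardware-agnostic.

### Correlograms and jitter correction

The raw correlogram of binned trains x, y is
λ_raw(τ) = Σ_t x(t)·y(t+τ) for τ = −L..+L bins, out-of-range products
contributing zero.  Default L = 50 bins (±100 ms); the analysis never
needs more than the κ_oscsync DFT span.

Jitter correction removes rate-driven chance coincidences.  Instead of
resampling surrogate trains, both trains are convolved with a
homogeneous kernel of width T_jitter = 6 ms — `round(T_jitter/Δ)` equal
taps summing to 1 (a 3-tap kernel at 2 ms bins) — and the correlogram
of the convolved trains is subtracted: λ = λ_raw − λ_jitter.  The
convolution identity equals the expectation over uniform re-drawing of
each spike time within the jitter window, at a fraction of the cost,
and is the only implementation provided.  Conventions:

* the kernel acts at the binned (2 ms) resolution, not at the raw
  sampling resolution; a sample-resolution kernel followed by binning
  is equivalent up to edge effects;
* convolution edges are zero-padded and the output keeps the input
  length ("same");
* *both* trains are convolved (some jitter-correction variants convolve
  only one side; the two-sided form is what the convolution identity
  for jointly jittered trains gives).

Useful exact consequences, used as test oracles: a single coincident
spike pair yields λ_jitter = [1,2,3,2,1]/9 over lags −2..+2 (the 3-tap
kernel's autocorrelation) and a normalized zero-lag peak of
1 − 1/3 = 2/3.

The pipeline path (`compute_metric_table`) evaluates all pairs and
trials with a batched FFT implementation; it reproduces the per-pair
functions to machine precision (tested), including the edge handling,
because the convolved trains are explicitly truncated back to the
trial length before correlating.

### Synchrony statistics

* **κ_sync** — the largest value of λ at lags within ±T_sync = 5 ms of
  zero (window inclusive in lag *time*: |l·Δ| ≤ T_sync, i.e. ±2 bins at
  2 ms), clamped at 0.  Ties in the reported argmax lag resolve to the
  smallest |lag|, negative first; the value itself is tie-free.
  κ_sync is a clamped max-statistic: under the null its mean is
  positively biased, which matters for interpreting raw values but
  cancels in the centered tensor.
* **κ_oscsync** — with DFT length N (default: the correlogram length,
  no padding), band edges in Hz map to bins via m = round(f·N·Δ)
  (round-half-even), and the band power Σ|DFT(m)|² between m_min and
  m_max — *including* the conjugate bins N−m, so a real tone's full
  power is counted — is divided by the total power Σ_n |DFT(n)|².
  The DC bin stays in the denominator by default; `exclude_dc=True`
  removes it from both sums.  The statistic is undefined (error) for an
  identically zero correlogram; the batched pipeline path reports 0
  for empty trials instead so a whole-session run does not abort.

### Tensor construction and centering

Values are assembled into x_ijk (pair × stimulus × repetition); missing
or duplicate cells are errors, never imputed.  On a homogeneous grid
with spacing d_grid, a pair is *neighboring* iff its Euclidean distance
is ≤ √2·d_grid — horizontal, vertical and diagonal neighbors — else
*remote*; a full 4×4 grid splits 42/78.  Separate analyses of the two
sets use `subset_tensor`.

Centering is sequential single-mode centering: for each mode in the
given order (default 1, 2, 3), the mean across that mode is subtracted
from the result of the previous centering.  No scaling is applied (a
hook exists but is off and excluded from all validation claims).
Sequential centering guarantees zero fiber means only for the mode
centered last; the earlier modes' residual means are reported by tests,
not asserted.  For an exactly trilinear tensor, centering is
factor-wise (each mode's centering centers the corresponding loading
columns), so planted low-rank structure survives centering with its
rank intact.

### PARAFAC by alternating least squares

The model x_ijk = Σ_{f=1..F} a_if·b_jf·c_kf + ε_ijk is fitted by
cycling conditional least squares for A, B, C (normal equations via the
Khatri-Rao product; a rank-deficient system falls back to the
pseudoinverse with a warning).  Convergence: the decrease of the
residual sum of squares per cycle falls below tol = 1e-8 relative to
‖X‖², or 2000 iterations.  The residual is monotone non-increasing by
construction and asserted in tests.

Indeterminacies are fixed by convention: B and C columns are scaled to
unit norm with magnitudes absorbed into A; each B and C column's sign
is flipped so its largest-|entry| is positive, flips absorbed into A;
components are ordered by ‖a_f‖ descending (cosmetic — the model has no
inherent order).  Initialisation is uniform random [0,1) for B and C,
with multi-start (default 10 independent starts) keeping the best-fit
run; all starts' final fits are reported.  A combined congruence below
−0.85 between two components triggers a two-factor-degeneracy warning
(not an error).

### Component-count selection

Two binding rules, evaluated on fits F = 1..F_max:

* **Scree rule** — the step to F is significant if its explained-
  variance gain is ≥ `scree_ratio` (default 0.1) × the largest earlier
  gain (EV(1) counts as the first gain).  Fitting an extra component
  into i.i.d. noise gains far less than fitting structure, so gains
  collapse past the true rank.  This rule presumes centered input — a
  dominant offset component would dwarf all later gains — which is how
  the pipeline always applies PARAFAC.
* **Congruence rule** — "correlated components" is operationalised as
  max off-diagonal |φ_A·φ_B·φ_C| > 0.85, where φ_M is the Tucker
  congruence (cosine) matrix of M's columns.  Overfactoring typically
  produces duplicated or degenerately cancelling components that this
  flags.

The chosen F is the largest candidate passing both; F = 1 always
passes.  Both traces are reported in full.  Neither rule alone is
reliable: the congruence rule misses extra noise components (which are
usually mutually *un*correlated), the scree rule alone can be fooled by
unequal component magnitudes.

### Validation

* **Split-half** — the tensor is split along the repetition mode by
  trial-number parity (odd/even), which interleaves the experiment's
  phases so both halves sample warm, deactivation and rewarm alike.
  Each half is fitted independently; components are aligned greedily on
  the pair×stimulus combined congruence and scored.  Because a
  trilinear component is invariant under jointly flipping two loading
  vectors' signs, and the repetition mode is not compared, the sign of
  a two-mode congruence product is not identifiable; the factor-match
  score over a proper subset of modes is therefore unsigned (in [0,1]),
  while the three-mode score is signed (in [−1,1]).
* **Residual bootstrap** — least squares is optimal under Gaussian
  errors, which synchrony residuals need not satisfy.  Residuals
  ε = X − x̂ from a baseline fit feed two error sets: values resampled
  from the empirical residual distribution, and draws from
  Normal(mean ε, sd ε).  Each replicate adds errors to the *model
  reconstruction* x̂ (parametric reading of "added to the original
  data"; the literal reading — data plus a second noise dose — is
  available via `target="data"`), refits, and scores the three-mode
  factor match to the baseline.  Agreement of the two score
  distributions indicates insensitivity to the error distribution's
  shape.

### PCA baseline

Mode-n matricization follows C order: rows are the chosen mode, columns
the remaining modes in increasing order with the later mode varying
fastest.  The default unfolding keeps repetitions as observations
(mode 3), where the bilinear model's failure to isolate the
deactivation time course is most visible; all modes are available.
PCA is a column-centered SVD; variance shares come from squared
singular values.  Note the unfolded SVD is the *optimal* rank-F matrix
approximation of that unfolding, so an F-component PARAFAC can only
match its explained variance up to the extra noise the SVD soaks up;
the multiway model's advantage shows in components-to-threshold and in
interpretability, not in raw fit at equal F.

## Synthetic data

`simulate_tensor` draws X = Σ_f a_f∘b_f∘c_f + ε with i.i.d. Gaussian ε
whose SD is specified relative to the signal SD, loading columns
re-drawn until all pairwise congruences are below a separation bound.
Ground-truth loadings are returned in the package normalization.

`simulate_experiment` emulates the deactivation experiment:

* 4×4 grid, 500 µm spacing, channel 5 dead (the choice of dead channel
  is arbitrary) — 15 live channels, 105 pairs;
* 8 stimuli (4 orientations × 2 directions); 8 s trials (2 s gray +
  2 s static + 4 s moving grating); 3 cycles × 7 repetitions per phase
  → repetitions 1–21 warm, 22–42 deactivation, 43–63 rewarm.
  Stimulus order randomisation within cycles is irrelevant downstream
  (the tensor is indexed by repetition number, not presentation time)
  and not modelled;
* per channel, homogeneous Poisson background (default 10 Hz;
  optionally stepped per trial epoch, off by default since no rates are
  available to match);
* synchrony by a shared-event mechanism: each planted *assembly* (a
  channel group) has a Poisson mother process at rate
  base × stimulus-tuning × phase-multiplier whose events are inserted
  into every member channel with independent Gaussian timing jitter
  (SD 1 ms — inside the ±5 ms κ_sync window but wider than one 2 ms
  bin, so peaks are realistic rather than single-bin).  The rate
  factorisation is exactly the trilinear structure the decomposition
  assumes, making assemblies recoverable as components;
* optional common sinusoidal rate modulation (default 40 Hz) of a
  channel group via thinning, with a shared random phase per trial,
  producing oscillatory synchrony for κ_oscsync.

Default assembly parameters (three assemblies of 4–5 channels,
shared-event rates 20–25 Hz, orientation tuning width 0.8 stimulus
steps, deactivation multipliers 0.2/0.4 for two assemblies and a
rewarm-enhanced third): the recordings this emulates are not public
and report no firing statistics, so absolute rates are the package's
own choice.  They were set so the centered synchrony tensor's
structured-variance share lands in the regime the original analysis
reported for its data (a few components explaining the bulk of the
variance); with weak or broadly tuned synchrony most of the planted
signal is DC that centering removes, and no decomposition method could
recover it.  A warning is raised if an assembly's peak injection rate
exceeds 3× the background rate (over 75% shared spikes).

**What passing tests show and do not show.**  The generator produces
Poisson backgrounds, exactly trilinear synchrony strength, stationary
rates within trials and i.i.d. cell noise.  Real recordings have
non-Poisson multi-unit statistics, rate nonstationarity, slow drifts,
and synchrony that need not factorise.  Passing tests therefore
demonstrate correctness of the estimators and the decomposition under
the model's own assumptions, not that cortical data satisfy them; the
split-half and bootstrap procedures are the in-package tools for
judging the latter on real data.

## Problem sizes

Unit and property tests use small fixtures (tensors around 20×8×30,
spiking experiments with 2–6 channels and 1–4 s trials) and 10–30 seeds
for statistical checks; the acceptance suite and `scripts/acceptance.py`
additionally run one full-geometry session (15 live channels,
8 stimuli, 63 repetitions, 8 s trials — a (105, 8, 63) tensor) through
the entire pipeline.  These sizes are the package's standing choices
for its own regression suite.

## Known limitations

* No missing-data handling in the tensor or the decomposition
  (PARAFAC-with-missing-values and weighted fits are out of scope).
* No Tucker3, non-negativity or orthogonality constraints, and no
  CORCONDIA diagnostic.
* The jitter correction implements only the convolution identity; no
  resampled surrogate correction.
* κ_oscsync's band-bin mapping is exact only when band edges fall near
  bin centres; N is configurable (zero padding) when finer frequency
  resolution is needed.
* The analysis window for the statistics defaults to the full trial;
  `compute_metric_table(window=(t0, t1))` restricts it to one epoch
  (e.g. the moving-grating interval) when desired.
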