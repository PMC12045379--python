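# Methods

This note documents the models, parameter choices and numerical conventions
used throughout `kinefp`, and what the synthetic-data tests do and do not
establish about real data.

## Generative model

Traces are simulated with a discrete-frame kinetic Monte Carlo scheme: at
each frame the molecule remains in its current state *i* with probability
`exp(-1/τᵢ)`, where `τᵢ` is the state lifetime in frames
(`τᵢ[s] / exposure`).  Dwell times are therefore geometric in frames with
mean close to `τᵢ`; we simulate directly in frame space rather than drawing
continuous exponential dwells and binning, because the discrete chain is
the model under which per-frame idealization operates.  The noiseless 0/1
path is scaled by the bound-state level and white Gaussian noise is added
per frame.  Defaults are the conditions used across the test suite:

| parameter   | default | meaning |
|-------------|---------|---------|
| `tau_bound` | 1.4 s   | mean bound-state (probe-on) lifetime |
| `tau_unbound` | 3.5 s | mean unbound lifetime at working probe concentration |
| `exposure`  | 0.1 s   | camera frame time |
| `n_frames`  | 2000    | 200 s observation per molecule |
| `bound_level` | 4000 counts | bound-state intensity over baseline |
| `noise_sigma` | 400 counts | per-frame Gaussian noise (trace SNR ~10) |

With these values a molecule shows ~40 binding events per 200 s, the
regime in which per-molecule kinetics become measurable.  Infinite
lifetimes are accepted (stay probability exactly 1, an absorbing state);
NaN or non-positive lifetimes are rejected.  Random draws are consumed in
a fixed order (conformational path if any, binding path, photobleach time
if enabled, noise), so a seed fully determines the trace.  Photobleaching
(measured in such experiments at ~10⁻³ s⁻¹, negligible against the
dissociation rates of interest) is off by default but available as an
exponential bleach channel.

**Bursting.**  A slow hidden accessible/blocked layer switches with its own
two-state chain (defaults 10 s accessible / 30 s blocked); association is
multiplied by `blocked_binding_factor` (default 0) during blocked periods,
dissociation is untouched.  `factor = 1` reduces exactly to the homogeneous
chain, which the tests verify distributionally.

**Nonspecific background traces.**  Negative-control traces are sparse
sticking events (Poisson arrivals at 0.008 s⁻¹, i.e. ~1.6 events per
200 s) with heavy-tailed lognormal durations (median 15 s, log-sd 1) and
lognormal amplitude scatter (log-sd 0.3).  These values were chosen once
to produce the few-events/long-dwells signature that kinetic filtering
must reject; they are not fitted to any dataset.

**Movies.**  Spots are unit-sum Gaussian PSFs (σ = 1 px by default) at
uniformly drawn centers separated by ≥ 4σ (rejection sampling; an explicit
override permits crowding), over a flat background (200 counts) with
per-pixel read noise of 106 counts — chosen so the background-subtracted
3×3 trace noise is ≈400 counts, matching the trace-level SNR ~10 of the
direct simulator.  What the movie generator does *not* emulate: EMCCD gain
statistics, the evanescent illumination profile, drift, flat-field
structure, or camera formats beyond multi-page TIFF.  Detection results on
these movies therefore demonstrate the pipeline's logic, not robustness to
instrument artifacts.

## Spot detection and trace extraction

The fluctuation map is the mean absolute frame-to-frame intensity change
per pixel; blinking spots stand out against both dark and constant-bright
background.  ROIs are 3×3 windows on local maxima that exceed
`mean + 4 × robust-sd` (MAD-scaled) of the map, greedily non-maximum-
suppressed at a 3 px minimum separation, ordered by descending peak with
row-major tie-breaks; centers keep ≥ 2 px from the border so the
background ring fits.  Traces are `Σ(3×3 window) − 9 × median(5×5∖3×3
ring)` per frame.  The ring median is robust to bleed-through from a
neighbouring spot, at a known cost: the spot's own PSF tail raises the
ring, and per-pixel noise mixes the ring order statistics, so the
extracted amplitude is a reproducible ~15–20% below the 3×3 PSF flux at
σ = 1 px.  Downstream kinetics depend only on level *separation*, not
absolute flux, so this bias is accepted; the test suite pins it with a
noise-aware oracle.  Two-channel colocalization is greedy
nearest-neighbour matching, closest pairs first, one-to-one, within a
caller-set radius; channel registration is assumed exact.

## Idealization

A two-state Gaussian-emission HMM is fitted by maximum-likelihood EM
(initial levels at the 10th/90th intensity percentiles, symmetric 0.1
transition probability, emission variance at the trace variance; ≤100
iterations, log-likelihood tolerance 10⁻⁶) and decoded with Viterbi —
marginal decoding would introduce single-frame flicker at dwell
boundaries.  If the fitted levels separate by less than one fitted noise
sd, the trace is declared single-state with zero transitions (constant
and pure-noise traces take this path).  No minimum event length or
smoothing is imposed; event filtering belongs to the threshold stage.
At the default conditions (separation/noise = 10) the Viterbi path is
essentially exact; on noiseless traces it equals midpoint thresholding
frame for frame.

Dwells are runs of constant state × exposure; the first and last runs are
flagged truncated and excluded from all fits, so k transitions yield
exactly k−1 complete dwells and the dwell table sums exactly to the trace
duration.

The per-trace fingerprint records N_b+d (state changes), the median bound
and unbound dwells, the maximum unbound dwell, the intensity levels and
two level-separation/noise summaries: `noise_to_signal` (pooled
within-state sd over level separation, the ratio as sometimes quoted) and
its reciprocal `snr`, which the filter thresholds reference.

## Dwell-time fitting

The empirical survival of complete dwells, normalized to [0, 1], is
evaluated on a fixed 100-point even time grid and fitted by

    S(t) = m·e^(−t/τ) + c             (order 1)
    S(t) = m·e^(−t/τ₁) + n·e^(−t/τ₂) + c   (order 2, τ₁ < τ₂ reported)

by least squares with inverse-variance (binomial, `S(1−S)/n` floored at
10⁻³) weights.  Conventions and why:

* **Fixed grid, not per-dwell points.**  The SSE of a fit evaluated at
  every sorted dwell has expectation ≈ Σ F(1−F)/n ≈ 1/6 *independent of
  n*, which would make an absolute SSE acceptance rule meaningless.  On a
  fixed grid the SSE shrinks as K/6n and the < 0.05 rule discriminates as
  intended for pooled samples (n ≳ 500).
* **Weighting.**  Unweighted least squares on the survival curve
  overweights the sparse tail; at 40 dwells/trace it inflates the lifetime
  CV from ~16% to ~20–22%.  Binomial weighting restores near
  maximum-likelihood efficiency (verified against the sample-mean MLE).
* **Offset c.**  Free within ±0.05 for pooled fits (it absorbs small
  normalization tail effects) but pinned to 0 for per-trace fits, where a
  free intercept cannot be constrained by ~40 dwells and measurably
  inflates variance and bias.
* **Model selection.**  Order 1 is kept iff SSE < 0.05 and R² > 0.99.  A
  Wald–Wolfowitz runs test on residual signs is computed and reported as a
  diagnostic, but does not gate selection: empirical-CDF residuals are
  Brownian-bridge-correlated at any sample size, so a runs test rejects
  even correctly specified models.  Order-2 fits use three quantile-based
  multi-starts, keeping the best SSE; amplitudes are constrained
  non-negative.
* **Resolution guard.**  A `min_dwell` cutoff (e.g. two frames) is
  available for real data with instrument dead time, but is *off* by
  default: at 0.1 s exposure a two-frame cutoff discards ~7% of dwells,
  biasing the fitted bound lifetime down ~3% and inflating the per-trace
  CV by ~3 points, while the idealizer resolves single-frame events at
  these noise levels.

Rate constants: `k_dis = 1/τ_bound` (weighted), `k_a = 1/(τ_unbound·c)`
with `c` the molar probe concentration, `K_D = k_dis/k_a` (the identity is
exact by construction).  Per-trace precision: traces with ≥ 5 complete
dwells of each kind are fitted individually; the CV (sd/mean) of the
fitted lifetimes across molecules is the headline per-molecule precision
statistic and follows 1/√n in the dwell count.

## Kinetic filtering and subpopulations

A trace is accepted iff every configured bound holds (missing statistics
fail configured bounds).  `optimize_thresholds` grid-searches quantile-
derived candidates over six dimensions (minimum N_b+d; maxima on the
unbound dwell median and maximum; minimum SNR; bounds on the bound-dwell
median), maximizing accepted positives subject to an expected
false-positive budget per field of view (default 2, the level of the
negative controls this filter is designed to hold); ties prefer stricter
thresholds in a fixed lexicographic order, so the result is deterministic.
No per-probe presets are shipped — the optimizer is the supported path.

Subpopulations are classified with a Gaussian mixture on
(log τ_on,median, log τ_off,median) — kinetic clusters separate in log
space — with deterministic initialization at the 25th/75th percentile
corners; one component is used when BIC prefers it, and with two, the
component with the smaller mean log bound dwell is labelled `transient`.
Two-channel joint accessibility reports the both/A-only/B-only/neither
fractions over colocalized molecules plus label-conditional coincidence;
spatial permutation of one channel provides the chance-level control.

## Burst detection

ISIs (event-end to next event-onset, identical to complete unbound
dwells) from *all* molecules are pooled and ranked once, with average
ranks on ties — a burst is a global property of the experiment, so
molecules with few events do not generate their own lenient null.  Within
a molecule, candidate runs are maximal stretches of consecutive ISIs each
≤ 40 s; the subinterval with maximal `RS = −log₁₀ P(rank sum)` is accepted
as a burst when `RS > α = 3` (p < 10⁻³), removed, and the flanks are
rescanned.  The rank-sum null is exact (iterated convolution) for runs of
≤ 10 ISIs and for pools of ≤ 256 ISIs — so small instances are exact at
any run length — and a continuity-corrected Gaussian otherwise.  A burst
spans from the event preceding its first ISI to the event following its
last, hence always ≥ 2 events.

Two consequences worth knowing.  First, the log10 convention makes α = 3 a
per-scan p < 10⁻³; with the ~10³ subintervals a 40-ISI run offers, this
holds the fraction of Poisson ISIs mislabelled as bursts at ~3% (a p<0.05
reading of the same cutoff mislabels ~19% and would defeat the
false-positive control).  Second, because ranking is global, bursts are
detectable only against a pool in which short ISIs are *unusual*: a single
homogeneously bursty condition whose event count is dominated by in-burst
ISIs will rank its own bursts near the middle.  The tests therefore pool
modulated molecules with a majority of slow-binding molecules, emulating
the multi-condition pooling the global method is designed for.  A warning
is emitted when probe binding is not ≥ 10× faster than the detected burst
timescale, since burst boundaries are then confounded with binding noise.

## Fano statistics

Spikes are binding-event onsets.  For each molecule, 100 windows of length
T are placed uniformly at random, fully inside the observation span;
`F = Var/E` of the pooled counts is reported (per-molecule Fano factors
are also returned), at T = 5, 10, 20 and 40 s by default.  The Poisson
reference simulates matched-rate trains and computes F identically.  The
95% Poisson band is `Γ(shape=(n−1)/2, scale=2/(n−1))` quantiles at
2.5/97.5% — χ²ₙ₋₁/(n−1) — evaluated at **n = windows per molecule**
(100), not the pooled window total: windows drawn from one trace overlap
and are strongly correlated, so the pooled count is not an honest sample
size and would give a severely anti-conservative band (for T = 40 s in a
200 s trace the effective information per molecule is ~5 independent
windows).  With the per-molecule n the band is exact for a single
molecule's sampling and conservative for pooled estimates; calibration is
verified in the regime where its assumption holds exactly (n iid Poisson
counts), and joint coverage across all four windows exceeds 95% for
matched Poisson simulations.

## Pipeline and reproducibility

Stages (simulate → idealize → fingerprint → fit → burst → fano) exchange
only files (CSV/TIFF/JSON) in the output directory, enabling partial
reruns; `summary.json` embeds the package version, master seed and a
configuration hash, and identical configuration + seed reproduces every
artifact byte for byte.  All randomness flows from
`numpy.random.default_rng` with child seeds drawn below 2³¹.

## Problem sizes used in the test suite

Simulation-heavy checks run at sizes chosen to make their statistical
tolerances meaningful while keeping the suite quick on one CPU: the
precision experiment uses the full 400 traces × 2000 frames; dwell-law
and transition-probability checks use ~10⁶-frame traces (≥10⁵ dwells);
Fano calibration uses 200 replicates of 20 molecules; burst false-positive
control uses 400 Poisson trains of ~40 events.  The acceptance script runs
the complete 400-trace precision experiment in a few seconds.

## Known limitations

* The movie generator's optics are deliberately idealized (see above);
  detection metrics on it are upper bounds for real movies.
* Extraction amplitude carries the documented ring-median bias; absolute
  photon-flux calibration is out of scope.
* The HMM assumes two states with Gaussian noise; multi-level or drifting
  baselines are not modelled.
* Burst detection inherits the global-ranking caveat above: sensitivity
  depends on the composition of the pooled ISI set.
* Experimental quantities that depend on real extract data (accepted
  counts per field of view, population percentages, probe-specific rate
  constants) are exposed as computations but validated only by
  generator-label and permutation oracles.
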