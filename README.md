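# kinefp

Single-molecule **kine**tic **f**inger**p**rinting analysis: simulation,
spot detection, two-state HMM idealization, dwell-time kinetics,
Rank-Surprise burst detection and Fano-factor statistics for
repeated-binding fluorescence data.

## The problem

In single-molecule pull-down/TIRF experiments, a short fluorophore-labelled
oligonucleotide probe binds *transiently and repeatedly* to each
surface-captured target molecule (for example a miRNA held in an
Argonaute complex).  Each molecule therefore produces an intensity-versus-
time trace that blinks between an unbound baseline and a bound level — a
*kinetic fingerprint* that distinguishes genuine targets (many short,
regular binding events) from nonspecific surface sticking (few, long,
irregular events).  Because one molecule is probed tens of times, kinetic
parameters can be estimated *per molecule* with useful precision, which in
turn reveals heterogeneity: distinct kinetic subpopulations, and slow
switching of a single molecule between high- and low-accessibility states
that makes its binding-event train *bursty*.

`kinefp` implements the full analysis chain, plus a generator that produces
ground-truth-labelled synthetic movies and traces with the statistical
structure the analysis assumes, so every stage is testable end to end.

## Models and statistics

* **Trace model** — discrete-frame two-state Markov chain: the per-frame
  probability of remaining in state *i* is
  `P(i→i) = exp(−1/τᵢ)` with `τᵢ` in frames (`τᵢ[s]/exposure`), so dwell
  times are geometric with mean ≈ `τᵢ`.  The 0/1 path is scaled by the
  bound-state intensity and white Gaussian noise is added.  A slow hidden
  accessible/blocked layer that gates association generates bursting.
* **Idealization** — maximum-likelihood two-state Gaussian-emission HMM
  (deterministic initialization, Viterbi decoding) converts each trace to a
  binary path; runs of constant state give dwell times, with the truncated
  first/last dwell excluded from fits.
* **Dwell-time kinetics** — the empirical survival of dwell times is fitted
  by `S(t) = m·e^(−t/τ) + c` or the two-component form
  `m·e^(−t/τ₁) + n·e^(−t/τ₂) + c` (weighted mean lifetime
  `(mτ₁+nτ₂)/(m+n)`); a single exponential is kept when SSE < 0.05 and
  R² > 0.99.  Rate constants follow as `k_dis = 1/τ_bound`,
  `k_a = 1/(τ_unbound·c_probe)`, `K_D = k_dis/k_a`.
* **Kinetic filtering** — per-trace fingerprints (event count N_b+d, median
  and maximum dwell times, level signal-to-noise) are thresholded to count
  accepted molecules; thresholds can be optimized against labelled
  negatives under a false-positive budget.
* **Burst detection** — inter-spike intervals (ISIs) from all molecules are
  ranked together; for a run of q consecutive ISIs with rank sum S the
  Rank-Surprise statistic `RS = −log₁₀ P(Σ of q uniform ranks ≤ S)` is
  maximized exhaustively, and runs with `RS > α` (default 3, i.e.
  p < 10⁻³; ISIs ≤ 40 s) are labelled bursts.
* **Fano factor** — `F(T) = Var(N_T)/E(N_T)` of event counts in randomly
  placed windows of length T (100 windows per molecule); `F = 1` for a
  Poisson process, with the 95% Poisson band given by the
  `Γ((n−1)/2, 2/(n−1))` quantiles (χ²ₙ₋₁/(n−1)).

## Worked example

```python
import kinefp as kf

cfg = kf.SimConfig(tau_bound=1.4, tau_unbound=3.5, n_frames=2000,
                   exposure=0.1, bound_level=4000.0, noise_sigma=400.0,
                   seed=7)
trace, truth = kf.simulate_two_state_trace(cfg)

ideal = kf.TwoStateHMM(trace).fit()
print(ideal.summary())

dwells = kf.extract_dwells(ideal)
fit_b = kf.ExponentialDwellModel(dwells.bound_dwells()).fit()
fit_u = kf.ExponentialDwellModel(dwells.unbound_dwells()).fit()
print(kf.compute_rate_constants(fit_b, fit_u, 50e-9).summary())
```

prints

```
Two-state HMM idealization
  frames:          2000
  exposure:        0.1 s
  unbound level:   -3.3 +/- 398.2
  bound level:     4017.1 +/- 408.6
  transitions:     74
  log-likelihood:  -15121.0
k_dis = 0.8001 /s
k_a   = 4.242e+06 /(M s) at 5e-08 M probe
K_D   = 1.886e-07 M
```

The HMM recovers the two intensity levels (≈0 and ≈4000 counts with
noise ≈400) and counts 74 binding/dissociation transitions in 200 s.  The
single-trace lifetimes (37 complete bound dwells here) carry ~1/√n
statistical scatter, so this molecule's `k_dis` of 0.80 s⁻¹ sits within
sampling error of the simulated 1/1.4 ≈ 0.71 s⁻¹; pooling dwells across
molecules (`select_cdf_model`) tightens the estimate to the percent level.

The same stages run from the shell over file artifacts:

```
kinefp run --config pipeline.yaml --seed 1 --out results/
kinefp detect --movie movie.tif --out rois.csv
kinefp extract --movie movie.tif --rois rois.csv --out traces/
```

`run` writes traces, dwell tables, fingerprints, pooled fits, burst and
Fano tables, and a `summary.json` with the accepted-molecule count, rate
constants and per-trace lifetime CVs.

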