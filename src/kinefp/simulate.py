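"""Kinetic Monte Carlo generators for single-molecule binding data.

The generative model is the discrete-frame two-state Markov chain used
throughout single-molecule kinetic fingerprinting: in each frame the molecule
stays in state *i* with probability ``exp(-1 / tau_i[frames])`` where
``tau_i[frames] = tau_i[seconds] / exposure``, i.e. dwell times are geometric
in frames with mean lifetime ~``tau_i``.  The noiseless 0/1 state path is
scaled by the bound-state intensity level and white Gaussian camera noise is
added per frame.

Random draws are consumed in a fixed, documented order so that a seed fully
determines the output:

1. one uniform per frame for the binding-state path (index 0 resolves a
   ``random`` initial state and is otherwise unused),
2. for modulated traces, one uniform per frame for the conformational layer,
   drawn *before* the binding uniforms,
3. one normal per frame for the additive noise.

Beyond the homogeneous chain the module provides the slow accessible/blocked
conformational modulation that produces bursting, mixed kinetic populations
with rare nonspecific "sticking" background traces, homogeneous Poisson event
trains, and full camera movies with Gaussian-PSF spots.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .containers import GroundTruth, IntensityTrace, MovieStack, SpikeTrain
from .exceptions import ConfigError, OvercrowdedFieldError

__all__ = [
    "SimConfig",
    "ModulatedSimConfig",
    "PopulationSpec",
    "SpotTruth",
    "simulate_two_state_trace",
    "simulate_bursting_trace",
    "simulate_population",
    "simulate_poisson_spike_train",
    "simulate_movie",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a homogeneous two-state trace.

    Attributes
    ----------
    tau_bound, tau_unbound : float
        Mean state lifetimes in seconds.  ``inf`` is allowed and makes the
        state absorbing (per-frame stay probability exactly 1); NaN or
        non-positive values are rejected.
    n_frames : int
        Trace length in frames (>= 2).
    exposure : float
        Seconds per frame.
    bound_level : float
        Bound-state intensity in camera counts above the unbound baseline.
    noise_sigma : float
        Per-frame Gaussian noise standard deviation, counts.
    seed : int or None
        Seed for the trace's own generator (ignored when an external
        generator is passed to the simulation functions).
    initial_state : {"random", "bound", "unbound"}
        ``random`` draws the initial state from the stationary occupancy
        ``tau_bound / (tau_bound + tau_unbound)``.
    photobleach_rate : float
        Optional exponential photobleaching rate (1/s); 0 disables it.  When
        active, a single bleach time is drawn (after the state path, before
        the noise) and the fluorescent signal is zeroed from that frame on.
    """

    tau_bound: float = 1.4
    tau_unbound: float = 3.5
    n_frames: int = 2000
    exposure: float = 0.1
    bound_level: float = 4000.0
    noise_sigma: float = 400.0
    seed: int | None = None
    initial_state: str = "random"
    photobleach_rate: float = 0.0

    def validate(self) -> None:
        for name in ("tau_bound", "tau_unbound"):
            v = getattr(self, name)
            if math.isnan(v) or v <= 0:
                raise ConfigError(f"{name} must be positive (got {v!r})")
        if self.exposure <= 0 or not math.isfinite(self.exposure):
            raise ConfigError("exposure must be positive and finite")
        if self.n_frames < 2:
            raise ConfigError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if self.initial_state not in ("random", "bound", "unbound"):
            raise ConfigError(f"unknown initial_state {self.initial_state!r}")
        if self.photobleach_rate < 0:
            raise ConfigError("photobleach_rate must be >= 0")

    # per-frame stay probabilities, exp(-1 / tau[frames])
    @property
    def p_stay_bound(self) -> float:
        return math.exp(-self.exposure / self.tau_bound)

    @property
    def p_stay_unbound(self) -> float:
        return math.exp(-self.exposure / self.tau_unbound)

    @property
    def stationary_bound(self) -> float:
        if math.isinf(self.tau_bound) and math.isinf(self.tau_unbound):
            return 0.5
        if math.isinf(self.tau_bound):
            return 1.0
        if math.isinf(self.tau_unbound):
            return 0.0
        return self.tau_bound / (self.tau_bound + self.tau_unbound)


@dataclass(frozen=True)
class ModulatedSimConfig:
    """Two-state binding under a slow accessible/blocked conformational layer.

    The hidden conformational state switches with mean lifetimes
    ``accessible_lifetime`` / ``blocked_lifetime`` (seconds).  Association is
    attempted at the base rate during accessible periods and at
    ``base x blocked_binding_factor`` during blocked periods; dissociation is
    unaffected.  ``blocked_binding_factor = 1`` reduces to the homogeneous
    model, ``0`` blocks binding completely.
    """

    base: SimConfig = field(default_factory=SimConfig)
    accessible_lifetime: float = 10.0
    blocked_lifetime: float = 30.0
    blocked_binding_factor: float = 0.0

    def validate(self) -> None:
        self.base.validate()
        for name in ("accessible_lifetime", "blocked_lifetime"):
            v = getattr(self, name)
            if math.isnan(v) or v <= 0:
                raise ConfigError(f"{name} must be positive (got {v!r})")
        if not 0.0 <= self.blocked_binding_factor <= 1.0:
            raise ConfigError("blocked_binding_factor must lie in [0, 1]")


@dataclass(frozen=True)
class PopulationSpec:
    """A mixture of trace-generating components plus nonspecific background.

    ``components`` is a sequence of ``(config, fraction)`` pairs where each
    config is a :class:`SimConfig` or :class:`ModulatedSimConfig`.  Fractions
    must sum to 1.  Each generated trace is, independently with probability
    ``background_trace_rate``, replaced by a nonspecific "sticking" trace:
    rare events (Poisson, ``background_event_rate`` per second) with
    heavy-tailed lognormal durations and variable amplitude -- the signature
    that kinetic filtering must reject.
    """

    components: tuple = ((SimConfig(), 1.0),)
    n_traces: int = 100
    background_trace_rate: float = 0.0
    background_event_rate: float = 0.008
    background_dwell_median: float = 15.0
    background_dwell_sigma: float = 1.0

    def validate(self) -> None:
        if len(self.components) == 0:
            raise ConfigError("components must be non-empty")
        fracs = [f for _, f in self.components]
        if any(f < 0 for f in fracs) or abs(sum(fracs) - 1.0) > 1e-9:
            raise ConfigError("component fractions must be >= 0 and sum to 1")
        for cfg, _ in self.components:
            cfg.validate()
        if self.n_traces < 1:
            raise ConfigError("n_traces must be >= 1")
        if not 0.0 <= self.background_trace_rate <= 1.0:
            raise ConfigError("background_trace_rate must lie in [0, 1]")


@dataclass
class SpotTruth:
    """Ground truth for one rendered movie spot."""

    row: float
    col: float
    truth: GroundTruth
    label: str
    window_capture_fraction: float


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _initial_state(config: SimConfig, u0: float) -> int:
    if config.initial_state == "bound":
        return 1
    if config.initial_state == "unbound":
        return 0
    return 1 if u0 < config.stationary_bound else 0


def _state_path(u: np.ndarray, p_stay: tuple[float, float], s0: int) -> np.ndarray:
    """Walk the two-state chain given per-frame uniforms.

    ``u[t]`` governs the transition from frame ``t-1`` to ``t``: the state
    flips iff ``u[t] > p_stay[state]``.  Vectorized over dwell runs, which is
    equivalent to (and ~100x faster than) the frame-by-frame loop.
    """
    n = u.size
    states = np.empty(n, dtype=np.int8)
    # precomputed flip indicators for either possible current state
    flip = (u > p_stay[0], u > p_stay[1])
    t, s = 0, s0
    while t < n:
        seg = flip[s][t + 1 :]
        j = int(np.argmax(seg)) if seg.size else 0
        if seg.size == 0 or not seg[j]:
            states[t:] = s
            break
        end = t + 1 + j
        states[t:end] = s
        s = 1 - s
        t = end
    return states


# ---------------------------------------------------------------------------
# trace generators
# ---------------------------------------------------------------------------


def simulate_two_state_trace(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one homogeneous two-state intensity trace.

    Returns the noisy trace and its ground truth.  Identical config and seed
    give bit-identical output.
    """
    config.validate()
    rng = _as_rng(config.seed if rng is None else rng)
    n = config.n_frames

    u = rng.uniform(size=n)  # draw 1: state path
    s0 = _initial_state(config, u[0])
    states = _state_path(u, (config.p_stay_unbound, config.p_stay_bound), s0)

    signal = states.astype(float) * config.bound_level
    if config.photobleach_rate > 0:  # draw 2 (optional): bleach time
        t_bleach = rng.exponential(1.0 / config.photobleach_rate)
        k = int(t_bleach / config.exposure)
        if k < n:
            signal[k:] = 0.0
    noise = rng.normal(0.0, config.noise_sigma, size=n)  # draw 3: noise

    trace = IntensityTrace(intensity=signal + noise, exposure=config.exposure)
    truth = GroundTruth(
        states=states,
        exposure=config.exposure,
        params={"config": config, "kind": "two_state"},
    )
    return trace, truth


def simulate_bursting_trace(
    config: ModulatedSimConfig, rng: np.random.Generator | None = None
) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate a trace whose association rate is gated by a slow hidden state.

    The conformational layer (accessible/blocked) evolves as its own two-state
    chain; binding proceeds as in :func:`simulate_two_state_trace` except that
    the per-frame association probability is multiplied by
    ``blocked_binding_factor`` during blocked periods.
    """
    config.validate()
    base = config.base
    rng = _as_rng(base.seed if rng is None else rng)
    n = base.n_frames
    exp_t = base.exposure

    # draw 1: conformational path
    u_c = rng.uniform(size=n)
    p_acc = math.exp(-exp_t / config.accessible_lifetime)
    p_blk = math.exp(-exp_t / config.blocked_lifetime)
    frac_acc = config.accessible_lifetime / (
        config.accessible_lifetime + config.blocked_lifetime
    )
    c0 = 1 if u_c[0] < frac_acc else 0
    # conformation: 1 = accessible (stays with p_acc), 0 = blocked
    conf = _state_path(u_c, (p_blk, p_acc), c0)

    # draw 2: binding path (frame loop; the association prob is time-varying)
    u_b = rng.uniform(size=n)
    p_stay_b = base.p_stay_bound
    p_bind_open = 1.0 - base.p_stay_unbound
    f = config.blocked_binding_factor
    states = np.empty(n, dtype=np.int8)
    s = _initial_state(base, u_b[0]) if conf[0] == 1 or f > 0 else 0
    states[0] = s
    for t in range(1, n):
        if s == 1:
            if u_b[t] > p_stay_b:
                s = 0
        else:
            p_bind = p_bind_open * (1.0 if conf[t] == 1 else f)
            if u_b[t] < p_bind:
                s = 1
        states[t] = s

    noise = rng.normal(0.0, base.noise_sigma, size=n)  # draw 3
    trace = IntensityTrace(
        intensity=states * base.bound_level + noise, exposure=exp_t
    )
    truth = GroundTruth(
        states=states,
        exposure=exp_t,
        params={"config": config, "kind": "bursting"},
        conformation=conf,
    )
    return trace, truth


def _simulate_background_trace(
    spec: PopulationSpec, template: SimConfig, rng: np.random.Generator
) -> tuple[IntensityTrace, GroundTruth]:
    """Nonspecific sticking: sparse, long, irregular intensity excursions."""
    n, exp_t = template.n_frames, template.exposure
    duration = n * exp_t
    n_events = rng.poisson(spec.background_event_rate * duration)
    starts = np.sort(rng.uniform(0.0, duration, size=n_events))
    durations = rng.lognormal(
        math.log(spec.background_dwell_median), spec.background_dwell_sigma,
        size=n_events,
    )
    amps = template.bound_level * rng.lognormal(0.0, 0.3, size=n_events)

    signal = np.zeros(n)
    occupied = np.zeros(n, dtype=np.int8)
    for t0, d, a in zip(starts, durations, amps):
        i0 = int(t0 / exp_t)
        i1 = min(n, i0 + max(1, int(round(d / exp_t))))
        signal[i0:i1] = a  # later arrivals overwrite overlaps
        occupied[i0:i1] = 1
    noise = rng.normal(0.0, template.noise_sigma, size=n)
    trace = IntensityTrace(intensity=signal + noise, exposure=exp_t)
    truth = GroundTruth(
        states=occupied,
        exposure=exp_t,
        params={"kind": "background", "n_events": n_events},
    )
    return trace, truth


def simulate_population(
    spec: PopulationSpec, seed=None
) -> list[tuple[IntensityTrace, GroundTruth, str]]:
    """Draw ``spec.n_traces`` traces i.i.d. from the mixture.

    Returns ``(trace, truth, label)`` triples where ``label`` is
    ``"component_<i>"`` or ``"background"``.
    """
    spec.validate()
    rng = _as_rng(seed)
    fracs = np.array([f for _, f in spec.components])
    out = []
    for _ in range(spec.n_traces):
        child = np.random.default_rng(rng.integers(0, 2**31 - 1))
        idx = int(rng.choice(len(fracs), p=fracs))
        cfg = spec.components[idx][0]
        base = cfg.base if isinstance(cfg, ModulatedSimConfig) else cfg
        if rng.uniform() < spec.background_trace_rate:
            trace, truth = _simulate_background_trace(spec, base, child)
            label = "background"
        elif isinstance(cfg, ModulatedSimConfig):
            trace, truth = simulate_bursting_trace(cfg, child)
            label = f"component_{idx}"
        else:
            trace, truth = simulate_two_state_trace(cfg, child)
            label = f"component_{idx}"
        out.append((trace, truth, label))
    return out


def simulate_poisson_spike_train(
    rate: float, duration: float, seed=None, molecule_id: int | str = 0
) -> SpikeTrain:
    """Homogeneous Poisson point events on ``[0, duration]``.

    The event count is Poisson(rate x duration); given the count, event times
    are i.i.d. uniform (the standard conditional construction).
    """
    if rate < 0:
        raise ConfigError("rate must be >= 0")
    if duration <= 0:
        raise ConfigError("duration must be positive")
    rng = _as_rng(seed)
    n = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n))
    return SpikeTrain.from_times(times, duration, molecule_id=molecule_id)


# ---------------------------------------------------------------------------
# movies
# ---------------------------------------------------------------------------


def _gaussian_patch(
    sigma: float, row: float, col: float, shape: tuple[int, int]
) -> tuple[slice, slice, np.ndarray]:
    """Unit-sum Gaussian PSF footprint clipped to the image."""
    r = int(math.ceil(4 * sigma)) + 1
    r0, r1 = max(0, int(row) - r), min(shape[0], int(row) + r + 1)
    c0, c1 = max(0, int(col) - r), min(shape[1], int(col) + r + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    w = np.exp(-((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2))
    return slice(r0, r1), slice(c0, c1), w / w.sum()


def simulate_movie(
    spec: PopulationSpec,
    shape: tuple[int, int] = (64, 64),
    psf_sigma: float = 1.0,
    background: float = 200.0,
    read_noise: float = 106.0,
    seed=None,
    min_separation: float | None = None,
    allow_overlap: bool = False,
    channel: str = "ch0",
) -> tuple[MovieStack, list[SpotTruth]]:
    """Render a population of molecules as a noisy TIRF-style movie.

    Each molecule's noiseless signal (0/1 state path x bound level) is
    rendered as a unit-sum 2-D Gaussian of width ``psf_sigma`` at a random
    center; a flat ``background`` plus per-pixel Gaussian ``read_noise`` is
    added.  The default read noise of 106 counts makes the 9-pixel
    background-subtracted trace noise ~400 counts for a 4000-count spot,
    i.e. a trace signal-to-noise near 10.

    Spot centers are drawn uniformly at least 3 px inside the border and, by
    default, at least ``4 x psf_sigma`` apart (rejection sampling; raises
    :class:`OvercrowdedFieldError` if the layout cannot be satisfied, unless
    ``allow_overlap``).

    Draw order: spot centers, then each spot's trace (own child generator),
    then pixel noise.

    Returns the movie (float counts, >= 0) and per-spot ground truth
    including the fraction of PSF flux captured by the 3x3 window at the
    rounded center.
    """
    spec.validate()
    if shape[0] < 8 or shape[1] < 8:
        raise ConfigError("movie frame must be at least 8x8 pixels")
    rng = _as_rng(seed)
    sep = 4.0 * psf_sigma if min_separation is None else min_separation

    # noiseless population traces (no per-frame camera noise; noise is per pixel)
    quiet = PopulationSpec(
        components=tuple(
            (_without_noise(cfg), f) for cfg, f in spec.components
        ),
        n_traces=spec.n_traces,
        background_trace_rate=spec.background_trace_rate,
        background_event_rate=spec.background_event_rate,
        background_dwell_median=spec.background_dwell_median,
        background_dwell_sigma=spec.background_dwell_sigma,
    )

    margin = 3.0
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < spec.n_traces:
        attempts += 1
        if attempts > 1000 * spec.n_traces:
            raise OvercrowdedFieldError(
                f"cannot place {spec.n_traces} spots with separation {sep:g} px "
                f"in a {shape[0]}x{shape[1]} field"
            )
        r = rng.uniform(margin, shape[0] - 1 - margin)
        c = rng.uniform(margin, shape[1] - 1 - margin)
        if allow_overlap or all(
            (r - r2) ** 2 + (c - c2) ** 2 >= sep**2 for r2, c2 in centers
        ):
            centers.append((r, c))

    traces = simulate_population(quiet, seed=rng)
    first_cfg = spec.components[0][0]
    base = first_cfg.base if isinstance(first_cfg, ModulatedSimConfig) else first_cfg
    n_frames, exposure = base.n_frames, base.exposure

    movie = np.full((n_frames, *shape), float(background), dtype=np.float64)
    spots: list[SpotTruth] = []
    for (r, c), (trace, truth, label) in zip(centers, traces):
        rows, cols, w = _gaussian_patch(psf_sigma, r, c, shape)
        movie[:, rows, cols] += trace.intensity[:, None, None] * w[None]
        ri, ci = int(round(r)), int(round(c))
        win = w[
            max(0, ri - 1 - rows.start) : ri + 2 - rows.start,
            max(0, ci - 1 - cols.start) : ci + 2 - cols.start,
        ]
        spots.append(
            SpotTruth(
                row=r, col=c, truth=truth, label=label,
                window_capture_fraction=float(win.sum()),
            )
        )
    movie += rng.normal(0.0, read_noise, size=movie.shape)
    np.clip(movie, 0.0, None, out=movie)
    stack = MovieStack(
        data=movie.astype(np.float32), exposure=exposure, channel=channel
    )
    return stack, spots


def _without_noise(cfg):
    if isinstance(cfg, ModulatedSimConfig):
        return replace(cfg, base=replace(cfg.base, noise_sigma=0.0))
    return replace(cfg, noise_sigma=0.0)
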