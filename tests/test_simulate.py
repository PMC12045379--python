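"""Generator contracts: transition probabilities, dwell laws, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

import kinefp as kf
from kinefp.exceptions import ConfigError, OvercrowdedFieldError


class TestTwoStateTrace:
    def test_stay_probability_matches_closed_form(self):
        # tau_b = 14 frames -> empirical bound->bound frequency = exp(-1/14)
        cfg = kf.SimConfig(tau_bound=1.4, tau_unbound=3.5, n_frames=2 * 10**6,
                           exposure=0.1, seed=4)
        _, truth = kf.simulate_two_state_trace(cfg)
        s = truth.states
        emp = np.mean(s[1:][s[:-1] == 1] == 1)
        assert emp == pytest.approx(math.exp(-1 / 14), abs=1e-3)

    def test_two_levels_and_dwell_means(self):
        cfg = kf.SimConfig(n_frames=200000, seed=5)
        trace, truth = kf.simulate_two_state_trace(cfg)
        ideal = kf.IdealizedTrace(
            states=truth.states, means=np.array([0.0, 4000.0]),
            sds=np.array([400.0, 400.0]), log_likelihood=0.0, exposure=0.1,
        )
        dt = kf.extract_dwells(ideal)
        # geometric dwells have mean exposure/(1 - exp(-exposure/tau)),
        # slightly above tau; allow sampling error on top
        for state_mean, tau in ((dt.bound_dwells().mean(), 1.4),
                                (dt.unbound_dwells().mean(), 3.5)):
            expected = 0.1 / (1 - math.exp(-0.1 / tau))
            assert state_mean == pytest.approx(expected, rel=0.05)
        # intensity clusters near 0 and 4000
        b = trace.intensity[truth.states == 1]
        u = trace.intensity[truth.states == 0]
        assert abs(b.mean() - 4000) < 20 and abs(u.mean()) < 20

    def test_dwells_geometric(self):
        cfg = kf.SimConfig(tau_bound=0.5, tau_unbound=0.5, n_frames=12 * 10**5,
                           exposure=0.1, seed=6)
        _, truth = kf.simulate_two_state_trace(cfg)
        ideal = kf.IdealizedTrace(
            states=truth.states, means=np.array([0.0, 1.0]),
            sds=np.array([1.0, 1.0]), log_likelihood=0.0, exposure=0.1,
        )
        frames = np.round(kf.extract_dwells(ideal).bound_dwells() / 0.1)
        n = frames.size
        assert n > 10**5
        p_stay = math.exp(-1 / 5)
        # KS distance between the ECDF and the geometric CDF evaluated on
        # the integer support; the continuous KS critical value at
        # alpha = 0.01 (1.628/sqrt(n)) is conservative for a discrete law
        ks_d = 0.0
        for k in np.unique(frames):
            ecdf = np.mean(frames <= k)
            cdf = 1 - p_stay ** k
            ks_d = max(ks_d, abs(ecdf - cdf))
        assert ks_d < 1.628 / math.sqrt(n)

    def test_seed_determinism(self):
        cfg = kf.SimConfig(seed=42)
        t1, g1 = kf.simulate_two_state_trace(cfg)
        t2, g2 = kf.simulate_two_state_trace(cfg)
        np.testing.assert_array_equal(t1.intensity, t2.intensity)
        np.testing.assert_array_equal(g1.states, g2.states)

    def test_absorbing_unbound_state(self):
        cfg = kf.SimConfig(tau_unbound=math.inf, initial_state="unbound",
                           n_frames=5000, seed=1)
        trace, truth = kf.simulate_two_state_trace(cfg)
        assert truth.states.sum() == 0
        assert truth.spike_train().n_events == 0
        assert trace.intensity.std() == pytest.approx(400, rel=0.1)

    def test_noise_calibration(self):
        cfg = kf.SimConfig(tau_unbound=math.inf, initial_state="unbound",
                           n_frames=2 * 10**5, noise_sigma=400.0, seed=2)
        trace, _ = kf.simulate_two_state_trace(cfg)
        assert trace.intensity.std() == pytest.approx(400.0, rel=0.02)

    @pytest.mark.parametrize(
        "bad", [
            dict(tau_bound=0.0), dict(tau_bound=-1.0),
            dict(tau_unbound=math.nan), dict(n_frames=1),
            dict(exposure=0.0), dict(noise_sigma=-1.0),
            dict(initial_state="sideways"),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            kf.simulate_two_state_trace(kf.SimConfig(**bad))


class TestModulatedTrace:
    def test_degenerate_factor_one_matches_homogeneous(self):
        # blocked_binding_factor=1 must reduce to the homogeneous chain:
        # compare event-count distributions by KS
        base = kf.SimConfig(tau_bound=0.5, tau_unbound=1.5, n_frames=2000,
                            exposure=0.1)
        mod = kf.ModulatedSimConfig(base=base, accessible_lifetime=10.0,
                                    blocked_lifetime=30.0,
                                    blocked_binding_factor=1.0)
        rng = np.random.default_rng(9)
        n_mod = [kf.simulate_bursting_trace(mod, rng)[1].spike_train().n_events
                 for _ in range(300)]
        n_hom = [kf.simulate_two_state_trace(base, rng)[1].spike_train().n_events
                 for _ in range(300)]
        assert stats.ks_2samp(n_mod, n_hom).pvalue > 0.01

    def test_blocked_occupancy(self):
        # accessible 10 s / blocked 30 s, factor 0: ~75% of time eventless
        mod = kf.ModulatedSimConfig(
            base=kf.SimConfig(n_frames=5 * 10**5, exposure=0.1),
            accessible_lifetime=10.0, blocked_lifetime=30.0,
            blocked_binding_factor=0.0,
        )
        _, truth = kf.simulate_bursting_trace(mod, np.random.default_rng(3))
        blocked_frac = 1.0 - truth.conformation.mean()
        assert blocked_frac == pytest.approx(0.75, abs=0.03)
        # no binding transitions start while blocked
        starts = np.flatnonzero(np.diff(truth.states) == 1) + 1
        assert np.all(truth.conformation[starts] == 1)

    def test_bursting_overdispersion(self):
        mod = kf.ModulatedSimConfig(
            base=kf.SimConfig(tau_bound=0.5, tau_unbound=2.0, n_frames=3000,
                              exposure=0.1),
            accessible_lifetime=10.0, blocked_lifetime=30.0,
            blocked_binding_factor=0.0,
        )
        rng = np.random.default_rng(4)
        trains = [
            kf.simulate_bursting_trace(mod, rng)[1].spike_train(m)
            for m in range(120)
        ]
        fanos = [kf.fano_factor(trains, T, 100, seed=5).fano
                 for T in (5.0, 10.0, 20.0, 40.0)]
        assert all(f > 1 for f in fanos)
        assert all(b >= a for a, b in zip(fanos, fanos[1:]))


class TestPopulation:
    def test_mixture_counts(self):
        spec = kf.PopulationSpec(
            components=((kf.SimConfig(tau_bound=0.2, n_frames=100), 0.5),
                        (kf.SimConfig(tau_bound=20.0, n_frames=100), 0.5)),
            n_traces=1000,
        )
        sims = kf.simulate_population(spec, seed=8)
        n0 = sum(1 for _, _, lab in sims if lab == "component_0")
        # binomial 99% interval around 500
        assert abs(n0 - 500) < 2.58 * math.sqrt(1000 * 0.25)

    def test_single_component_single_label(self):
        spec = kf.PopulationSpec(
            components=((kf.SimConfig(n_frames=100), 1.0),), n_traces=20
        )
        labels = {lab for _, _, lab in kf.simulate_population(spec, seed=1)}
        assert labels == {"component_0"}

    def test_background_traces_sparse_and_long(self):
        spec = kf.PopulationSpec(
            components=((kf.SimConfig(), 1.0),), n_traces=50,
            background_trace_rate=1.0,
        )
        sims = kf.simulate_population(spec, seed=2)
        events = [truth.spike_train().n_events for _, truth, _ in sims]
        assert all(lab == "background" for _, _, lab in sims)
        assert np.mean(events) < 5  # rare sticking, not repeated binding

    def test_empty_components_rejected(self):
        with pytest.raises(ConfigError):
            kf.PopulationSpec(components=(), n_traces=5).validate()


class TestPoissonTrain:
    def test_zero_rate_empty(self):
        assert kf.simulate_poisson_spike_train(0.0, 100.0, seed=1).n_events == 0

    def test_moments(self):
        rng = np.random.default_rng(5)
        counts = [
            kf.simulate_poisson_spike_train(0.2, 200.0, seed=rng).n_events
            for _ in range(10**4)
        ]
        assert np.mean(counts) == pytest.approx(40, rel=0.02)
        assert np.var(counts) == pytest.approx(40, rel=0.06)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            kf.simulate_poisson_spike_train(-1.0, 10.0)

    def test_seed_determinism(self):
        a = kf.simulate_poisson_spike_train(0.5, 50.0, seed=7)
        b = kf.simulate_poisson_spike_train(0.5, 50.0, seed=7)
        np.testing.assert_array_equal(a.onsets, b.onsets)


class TestMovie:
    def test_duration_bookkeeping(self):
        spec = kf.PopulationSpec(
            components=((kf.SimConfig(n_frames=2000, exposure=0.1), 1.0),),
            n_traces=3,
        )
        movie, spots = kf.simulate_movie(spec, shape=(32, 32), seed=1)
        assert movie.duration == pytest.approx(200.0)
        assert len(spots) == 3

    def test_zero_spots_noise_floor(self):
        spec = kf.PopulationSpec(
            components=((kf.SimConfig(n_frames=300), 1.0),), n_traces=1
        )
        movie, _ = kf.simulate_movie(
            spec, shape=(32, 32), seed=2, read_noise=50.0
        )
        # remove the single spot's contribution by looking far away: build a
        # pure-background movie instead via an absorbing, never-bound config
        quiet = kf.PopulationSpec(
            components=((kf.SimConfig(n_frames=300, tau_unbound=math.inf,
                                      initial_state="unbound"), 1.0),),
            n_traces=1,
        )
        movie, _ = kf.simulate_movie(quiet, shape=(32, 32), seed=2,
                                     read_noise=50.0)
        fmap = kf.compute_fluctuation_map(movie)
        # mean |diff| of N(0, sigma*sqrt(2)) = 2*sigma/sqrt(pi)
        expected = 2 * 50.0 / math.sqrt(math.pi)
        assert fmap.data.mean() == pytest.approx(expected, rel=0.05)

    def test_overcrowded_layout_raises(self):
        spec = kf.PopulationSpec(
            components=((kf.SimConfig(n_frames=50), 1.0),), n_traces=200
        )
        with pytest.raises(OvercrowdedFieldError):
            kf.simulate_movie(spec, shape=(16, 16), seed=1)
        # explicit override permits it
        movie, spots = kf.simulate_movie(spec, shape=(16, 16), seed=1,
                                         allow_overlap=True)
        assert len(spots) == 200
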