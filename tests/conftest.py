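"""Shared fixtures: simulated datasets reused across test modules.

Everything is generated programmatically with fixed seeds; session scope
keeps the expensive simulations (HMM idealization of hundreds of traces)
to a single run per suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import kinefp as kf
from kinefp.idealize import stats_frame


def idealize_population(spec: kf.PopulationSpec, seed: int):
    """Simulate a population and run the full idealization stage."""
    sims = kf.simulate_population(spec, seed=seed)
    ideals, tables, stats = [], [], []
    for i, (trace, truth, label) in enumerate(sims):
        ideal = kf.TwoStateHMM(trace).fit()
        table = kf.extract_dwells(ideal)
        stats.append(
            kf.compute_fingerprint_stats(ideal, table, trace,
                                         trace_id=i, label=label)
        )
        ideals.append(ideal)
        tables.append(table)
    return sims, ideals, tables, stats_frame(stats)


@pytest.fixture(scope="session")
def precision_run():
    """The 400-trace repeated-binding precision simulation, idealized.

    Conditions: 2000 frames at 0.1 s, lifetimes 1.4 s (bound) / 3.5 s
    (unbound), bound level 4000 counts, noise sd 400 (trace SNR ~10).
    """
    spec = kf.PopulationSpec(
        components=((kf.SimConfig(), 1.0),), n_traces=400
    )
    return idealize_population(spec, seed=11)


@pytest.fixture(scope="session")
def labelled_pos_neg():
    """Idealized fingerprints for positive (repeated binding) and
    negative (nonspecific sticking only) populations of 150 traces each."""
    pos_spec = kf.PopulationSpec(
        components=((kf.SimConfig(), 1.0),), n_traces=150
    )
    neg_spec = kf.PopulationSpec(
        components=((kf.SimConfig(), 1.0),), n_traces=150,
        background_trace_rate=1.0,
    )
    _, _, _, pos = idealize_population(pos_spec, seed=21)
    _, _, _, neg = idealize_population(neg_spec, seed=22)
    return pos, neg


@pytest.fixture(scope="session")
def snr10_movie():
    """A 10-spot, 2000-frame movie at trace SNR ~10 with ground truth."""
    spec = kf.PopulationSpec(
        components=((kf.SimConfig(n_frames=2000), 1.0),), n_traces=10
    )
    return kf.simulate_movie(spec, shape=(64, 64), seed=3)
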