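"""End-to-end pipeline: simulate -> (detect/extract) -> idealize ->
fingerprint -> fit -> burst -> fano -> report.

Stages communicate only through files in the output directory (CSV for
tables and traces, TIFF for movies, JSON for the machine-readable summary),
so any stage can be re-run from its predecessors' artifacts.  Given the same
configuration and master seed the pipeline is idempotent: every output file
is re-derivable, and the summary embeds a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bursts import BurstParams, burst_statistics, global_rank_surprise
from .containers import GroundTruth, IntensityTrace
from .exceptions import InsufficientDataError, KinefpError
from .fano import DEFAULT_WINDOWS, fano_factor, poisson_fano_reference
from .fingerprint import FilterThresholds, filter_traces
from .idealize import TwoStateHMM, compute_fingerprint_stats, extract_dwells, stats_frame
from .kinetics import compute_rate_constants, per_trace_lifetimes, select_cdf_model
from .simulate import ModulatedSimConfig, PopulationSpec, SimConfig, simulate_population

log = logging.getLogger("kinefp.pipeline")

ALL_STAGES = ("simulate", "detect", "extract", "idealize", "fingerprint",
              "fit", "burst", "fano")
#: default stage set for trace-level runs (no movie rendering)
TRACE_STAGES = ("simulate", "idealize", "fingerprint", "fit", "burst", "fano")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`.

    All times are in seconds, intensities in camera counts, concentration in
    molar.  ``stages`` lists the enabled stages in pipeline order; later
    stages require the artifacts of earlier ones.
    """

    outdir: str = "kinefp_run"
    seed: int = 0
    stages: tuple = TRACE_STAGES

    # simulation
    n_traces: int = 100
    tau_bound: float = 1.4
    tau_unbound: float = 3.5
    n_frames: int = 2000
    exposure: float = 0.1
    bound_level: float = 4000.0
    noise_sigma: float = 400.0
    background_trace_rate: float = 0.0
    modulation: dict | None = None     # accessible_lifetime, blocked_lifetime,
                                       # blocked_binding_factor
    movie: dict | None = None          # render a movie instead of bare traces:
                                       # shape [rows, cols], psf_sigma,
                                       # background, read_noise (see
                                       # simulate_movie); requires the detect
                                       # and extract stages

    # detection
    detect_min_separation: float = 3.0
    detect_threshold: float | None = None   # None = mean + 4 robust sd

    # filtering
    thresholds: dict | None = None     # FilterThresholds fields; None = permissive

    # kinetics
    concentration: float = 50e-9       # molar probe concentration
    min_dwells_per_trace: int = 5

    # burst / fano
    max_isi_in_burst: float = 40.0
    burst_alpha: float = 3.0
    fano_windows: tuple = DEFAULT_WINDOWS
    fano_samples: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        from .io import read_yaml

        raw = read_yaml(path) or {}
        known = {f: raw[f] for f in raw if f in cls.__dataclass_fields__}
        unknown = set(raw) - set(known)
        if unknown:
            raise KinefpError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**known)
        cfg.stages = tuple(cfg.stages)
        cfg.fano_windows = tuple(cfg.fano_windows)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def sim_component(self):
        base = SimConfig(
            tau_bound=self.tau_bound,
            tau_unbound=self.tau_unbound,
            n_frames=self.n_frames,
            exposure=self.exposure,
            bound_level=self.bound_level,
            noise_sigma=self.noise_sigma,
        )
        if self.modulation:
            return ModulatedSimConfig(base=base, **self.modulation)
        return base


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Returns the machine-readable summary (also written to ``summary.json``).
    A stage failure raises with a diagnostic naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    summary: dict = {
        "kinefp_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": asdict(config),
        "stages_run": [],
    }
    state: dict = {}
    for stage in config.stages:
        if stage not in ALL_STAGES:
            raise KinefpError(f"unknown stage {stage!r}")
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, out, state, summary)
        except Exception as exc:
            raise KinefpError(
                f"stage {stage!r} failed: {exc}"
            ) from exc
        log.info("stage %s done in %.1f s", stage, time.time() - t0)
        summary["stages_run"].append(stage)

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable)
    )
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    spec = PopulationSpec(
        components=((cfg.sim_component(), 1.0),),
        n_traces=cfg.n_traces,
        background_trace_rate=cfg.background_trace_rate,
    )
    if cfg.movie is not None:
        from .io import write_movie_tiff
        from .simulate import simulate_movie

        kwargs = dict(cfg.movie)
        kwargs["shape"] = tuple(kwargs.get("shape", (64, 64)))
        movie, spots = simulate_movie(spec, seed=cfg.seed, **kwargs)
        write_movie_tiff(out / "movie.tif", movie)
        pd.DataFrame(
            [{"spot": i, "row": s.row, "col": s.col, "label": s.label}
             for i, s in enumerate(spots)]
        ).to_csv(out / "spots.csv", index=False)
        state["movie"] = movie
        state["spots"] = spots
        summary["n_spots"] = len(spots)
        return
    sims = simulate_population(spec, seed=cfg.seed)
    rows = []
    for i, (trace, truth, label) in enumerate(sims):
        rows.append(
            {"trace": i, "label": label,
             "true_n_events": int(truth.spike_train().n_events)}
        )
    intens = np.column_stack([t.intensity for t, _, _ in sims])
    pd.DataFrame(
        intens, columns=[f"trace_{i}" for i in range(len(sims))]
    ).assign(time_s=np.arange(cfg.n_frames) * cfg.exposure).to_csv(
        out / "traces.csv", index=False
    )
    pd.DataFrame(rows).to_csv(out / "trace_labels.csv", index=False)
    state["sims"] = sims
    summary["n_traces"] = len(sims)


def _stage_detect(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    from .imaging import compute_fluctuation_map, detect_rois
    from .io import write_roi_csv

    fmap = compute_fluctuation_map(state["movie"])
    rois = detect_rois(
        fmap, min_separation=cfg.detect_min_separation,
        threshold=cfg.detect_threshold,
    )
    write_roi_csv(out / "rois.csv", rois)
    state["rois"] = rois
    summary["n_rois"] = len(rois)


def _stage_extract(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    from .imaging import extract_trace

    movie = state["movie"]
    traces = [extract_trace(movie, roi) for roi in state["rois"]]
    if traces:
        pd.DataFrame(
            np.column_stack([t.intensity for t in traces]),
            columns=[f"trace_{i}" for i in range(len(traces))],
        ).assign(
            time_s=np.arange(movie.n_frames) * movie.exposure
        ).to_csv(out / "traces.csv", index=False)
    # downstream stages consume (trace, truth, label) triples; extracted
    # traces have no per-frame truth
    state["sims"] = [(t, None, f"roi_{i}") for i, t in enumerate(traces)]
    summary["n_traces"] = len(traces)


def _stage_idealize(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    sims = state["sims"]
    ideals, dwell_tables, stats = [], [], []
    for i, (trace, truth, label) in enumerate(sims):
        ideal = TwoStateHMM(trace).fit()
        dt = extract_dwells(ideal)
        stats.append(
            compute_fingerprint_stats(ideal, dt, trace, trace_id=i, label=label)
        )
        ideals.append(ideal)
        dwell_tables.append(dt)
    pd.concat(
        [dt.table.assign(trace=i) for i, dt in enumerate(dwell_tables)],
        ignore_index=True,
    ).to_csv(out / "dwells.csv", index=False)
    sf = stats_frame(stats)
    sf.to_csv(out / "fingerprints.csv", index=False)
    state.update(ideals=ideals, dwell_tables=dwell_tables, stats=sf)
    summary["mean_n_events"] = float(sf["n_events"].mean())


def _stage_fingerprint(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    thr = FilterThresholds(**(cfg.thresholds or {}))
    flags, n_acc = filter_traces(state["stats"], thr)
    state["accept"] = flags
    df = state["stats"].assign(accepted=flags)
    df.to_csv(out / "fingerprints.csv", index=False)
    summary["n_accepted"] = n_acc
    summary["thresholds"] = thr.as_dict()


def _stage_fit(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    accept = state.get("accept")
    tables = state["dwell_tables"]
    if accept is not None:
        tables = [t for t, ok in zip(tables, accept) if ok]
    if not tables:
        raise InsufficientDataError("no accepted traces to fit")
    bound = np.concatenate([t.bound_dwells() for t in tables])
    unbound = np.concatenate([t.unbound_dwells() for t in tables])
    fit_b = select_cdf_model(bound)
    fit_u = select_cdf_model(unbound)
    rates = compute_rate_constants(fit_b, fit_u, cfg.concentration)
    prec = per_trace_lifetimes(tables, min_dwells=cfg.min_dwells_per_trace)
    prec.table.to_csv(out / "per_trace_lifetimes.csv", index=False)
    pd.DataFrame(
        [
            {"state": "bound", **_fit_row(fit_b)},
            {"state": "unbound", **_fit_row(fit_u)},
        ]
    ).to_csv(out / "pooled_fits.csv", index=False)
    summary["pooled_tau_bound_s"] = fit_b.weighted_tau
    summary["pooled_tau_unbound_s"] = fit_u.weighted_tau
    summary["k_dis_per_s"] = rates.k_dis
    summary["k_a_per_M_s"] = rates.k_a
    summary["K_D_M"] = rates.k_d_eq
    summary["cv_tau_bound_pct"] = 100.0 * prec.cv_bound
    summary["cv_tau_unbound_pct"] = 100.0 * prec.cv_unbound
    summary["n_traces_in_cv"] = prec.n_included
    state["precision"] = prec


def _fit_row(fit) -> dict:
    return {
        "order": fit.order, "tau1_s": fit.tau1, "tau2_s": fit.tau2,
        "m": fit.m, "n": fit.n_amp, "c": fit.c,
        "weighted_tau_s": fit.weighted_tau, "sse": fit.sse,
        "r_squared": fit.r_squared, "n_dwells": fit.n_dwells,
    }


def _spike_trains(state, cfg):
    accept = state.get("accept")
    trains = []
    for i, ideal in enumerate(state["ideals"]):
        if accept is not None and not accept.iloc[i]:
            continue
        truth_like = GroundTruth(states=ideal.states, exposure=ideal.exposure)
        trains.append(truth_like.spike_train(molecule_id=i))
    return trains


def _stage_burst(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    trains = _spike_trains(state, cfg)
    params = BurstParams(
        max_isi_in_burst=cfg.max_isi_in_burst, alpha=cfg.burst_alpha
    )
    ann = global_rank_surprise(trains, params)
    bs = burst_statistics(ann)
    ann.to_frame().to_csv(out / "bursts.csv", index=False)
    state["trains"] = trains
    summary["n_bursts"] = ann.n_bursts
    summary["n_burst_isis"] = int(ann.labelled_isis("burst").size)
    summary["n_non_burst_isis"] = int(ann.labelled_isis("non_burst").size)
    if bs.burst_fit is not None:
        summary["burst_isi_tau_s"] = bs.burst_fit.tau1
    if bs.non_burst_fit is not None:
        summary["non_burst_isi_tau_s"] = bs.non_burst_fit.tau1


def _stage_fano(cfg: PipelineConfig, out: Path, state: dict, summary: dict):
    trains = state.get("trains") or _spike_trains(state, cfg)
    trains = [t for t in trains if t.n_events > 0]
    if not trains:
        raise InsufficientDataError("no event trains for Fano analysis")
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    duration = cfg.n_frames * cfg.exposure
    isis = np.concatenate(
        [t.onsets[1:] - t.ends[:-1] for t in trains if t.n_events >= 2]
    )
    rate = 1.0 / float(isis.mean()) if isis.size else 0.0
    for T in cfg.fano_windows:
        res = fano_factor(trains, T, cfg.fano_samples, seed=rng)
        rows.append({"label": "data", **_fano_row(res)})
        ref = poisson_fano_reference(
            rate, duration, len(trains), T, cfg.fano_samples, seed=rng
        )
        rows.append({"label": "poisson_reference", **_fano_row(ref)})
    table = pd.DataFrame(rows)
    table.to_csv(out / "fano.csv", index=False)
    summary["fano"] = rows


def _fano_row(res) -> dict:
    return {
        "T_s": res.T, "fano": res.fano, "n": res.n,
        "ci_low": res.ci_low, "ci_high": res.ci_high,
        "mean_count": res.mean_count, "n_molecules": res.n_molecules,
    }


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "extract": _stage_extract,
    "idealize": _stage_idealize,
    "fingerprint": _stage_fingerprint,
    "fit": _stage_fit,
    "burst": _stage_burst,
    "fano": _stage_fano,
}
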