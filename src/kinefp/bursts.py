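"""Global Rank-Surprise burst detection on binding-event trains.

Repeated probe binding to one molecule yields an event train whose
inter-spike intervals (ISIs; the gaps between consecutive events, equal to
complete unbound dwells) may cluster into *bursts* -- runs of unusually
short ISIs -- separated by quiet non-burst periods, the signature of a slow
conformational accessibility switch.

The Rank-Surprise (RS) statistic treats the ranks of ISIs as draws from a
discrete uniform null: for a run of q consecutive ISIs with rank sum S among
N pooled ISIs, ``RS = -log10 P(sum of q iid uniform{1..N} ranks <= S)``, so
the default cutoff alpha = 3 demands p < 1e-3 for each accepted burst --
strict enough that exhaustive maximization over all candidate runs keeps the
fraction of Poisson ISIs mislabelled as bursts at the few-percent level.  The
null CDF is exact (iterated convolution) for q <= 10 and a Gaussian
approximation with continuity correction beyond.  Ranking is *global*: ISIs
from all molecules are pooled and ranked once (average ranks on ties), so a
burst is defined relative to the whole experiment rather than each
molecule's own activity level.

Detection within each molecule follows the exhaustive-surprise scheme:
candidate runs are maximal stretches of consecutive ISIs each no longer than
``max_isi_in_burst``; within a run, the subinterval with the largest RS is
accepted as a burst if RS exceeds ``alpha``, removed, and the flanking
segments are rescanned.  A burst spans from the event preceding its first
ISI to the event following its last ISI (so every burst has >= 2 events).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpikeTrain
from .exceptions import ConfigError

__all__ = [
    "BurstParams",
    "Burst",
    "BurstAnnotation",
    "compute_isis",
    "rank_surprise_statistic",
    "global_rank_surprise",
    "burst_statistics",
]

#: run lengths up to this use the exact discrete rank-sum null ...
EXACT_Q_MAX = 10
#: ... as do pools of at most this many ISIs regardless of run length, so
#: that small instances are exact at any q (the Gaussian approximation is
#: reserved for long runs in large pools, where it is accurate and the
#: convolution would be costly)
EXACT_N_MAX = 256


def _use_exact(n_ranks: int, q) -> bool | np.ndarray:
    return (q <= EXACT_Q_MAX) | (n_ranks <= EXACT_N_MAX)


@dataclass(frozen=True)
class BurstParams:
    """RS detection parameters (defaults: max ISI 40 s, cutoff alpha = 3).

    ``alpha = 3`` corresponds to a per-scan significance of ``1e-3``
    (RS is in log10 units).
    """

    max_isi_in_burst: float = 40.0
    alpha: float = 3.0

    def __post_init__(self) -> None:
        if self.max_isi_in_burst <= 0:
            raise ConfigError("max_isi_in_burst must be positive")
        if self.alpha <= 0:
            raise ConfigError("alpha must be positive")


@dataclass
class Burst:
    """One detected burst within a molecule's event train."""

    molecule_id: int | str
    first_event: int      # index of the event preceding the first burst ISI
    last_event: int       # index of the event following the last burst ISI
    first_isi: int
    last_isi: int
    rs: float

    @property
    def n_isis(self) -> int:
        return self.last_isi - self.first_isi + 1


@dataclass
class BurstAnnotation:
    """Burst windows and per-ISI labels for a collection of molecules."""

    bursts: list[Burst]
    isi_labels: dict        # molecule_id -> array of "burst"/"non_burst"
    isis: dict              # molecule_id -> ISI array (s)
    params: BurstParams

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    def labelled_isis(self, label: str) -> np.ndarray:
        """All ISIs (s) carrying the given label, pooled over molecules."""
        out = [
            self.isis[m][self.isi_labels[m] == label] for m in self.isis
        ]
        return np.concatenate(out) if out else np.array([])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "molecule_id": b.molecule_id,
                    "first_event": b.first_event,
                    "last_event": b.last_event,
                    "rs": b.rs,
                    "n_isis": b.n_isis,
                }
                for b in self.bursts
            ]
        )


def compute_isis(train: SpikeTrain) -> np.ndarray:
    """Gaps between consecutive events: onset of k+1 minus end of k (s)."""
    if train.n_events < 2:
        return np.array([])
    return train.onsets[1:] - train.ends[:-1]


# ---------------------------------------------------------------------------
# rank-sum null distribution
# ---------------------------------------------------------------------------


@lru_cache(maxsize=64)
def _exact_cdf(n_ranks: int, q: int) -> np.ndarray:
    """CDF of the sum of q iid uniform{1..n_ranks}; index = sum value."""
    from scipy.signal import fftconvolve

    base = np.full(n_ranks, 1.0 / n_ranks)
    pmf = base
    for _ in range(q - 1):
        pmf = np.convolve(pmf, base) if n_ranks <= 256 else fftconvolve(pmf, base)
    pmf = np.clip(pmf, 0.0, None)
    cdf = np.zeros(q * n_ranks + 1)
    cdf[q:] = np.minimum(np.cumsum(pmf), 1.0)
    return cdf


def rank_sum_cdf(n_ranks: int, q: int, s: float) -> float:
    """P(sum of q iid uniform{1..n_ranks} ranks <= s).

    Exact (iterated convolution) for q <= EXACT_Q_MAX or pools of at most
    EXACT_N_MAX ISIs; Gaussian with continuity correction otherwise.
    With tie-averaged ranks ``s`` may be fractional; the exact CDF is
    evaluated at floor(s) (the largest achievable lattice sum below it).
    """
    if _use_exact(n_ranks, q):
        cdf = _exact_cdf(n_ranks, q)
        idx = min(int(math.floor(s)), q * n_ranks)
        return float(cdf[idx]) if idx >= 0 else 0.0
    mu = q * (n_ranks + 1) / 2.0
    var = q * (n_ranks**2 - 1) / 12.0
    z = (s + 0.5 - mu) / math.sqrt(var)
    return float(stats.norm.cdf(z))


def rank_surprise_statistic(n_ranks: int, q: int, rank_sum: float) -> float:
    """RS = -log10 P(rank sum of q uniform ranks <= observed sum)."""
    p = rank_sum_cdf(n_ranks, q, rank_sum)
    if p <= 0.0:
        return math.inf
    return -math.log10(p)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _segment_max_rs(
    csum: np.ndarray, lo: int, hi: int, n_ranks: int
) -> tuple[int, int, float] | None:
    """Subinterval of ranks[lo:hi] with maximal RS (vectorized scan).

    Ties in RS are broken toward the earliest start, then shortest run,
    which keeps detection deterministic.
    """
    L = hi - lo
    if L <= 0:
        return None
    # S[a, b] = rank sum of ISIs lo+a .. lo+b (valid for b >= a)
    S = csum[lo + 1 : hi + 1][None, :] - csum[lo:hi][:, None]
    a_idx, b_idx = np.triu_indices(L)
    q = b_idx - a_idx + 1
    s = S[a_idx, b_idx]
    p = np.empty(s.size)
    small = _use_exact(n_ranks, q)
    for qq in np.unique(q[small]):
        sel = q == qq
        cdf = _exact_cdf(n_ranks, int(qq))
        idx = np.clip(np.floor(s[sel]).astype(np.int64), 0, qq * n_ranks)
        p[sel] = cdf[idx]
    big = ~small
    if big.any():
        mu = q[big] * (n_ranks + 1) / 2.0
        var = q[big] * (n_ranks**2 - 1) / 12.0
        z = (s[big] + 0.5 - mu) / np.sqrt(var)
        p[big] = stats.norm.cdf(z)
    with np.errstate(divide="ignore"):
        rs = -np.log10(p)
    k = int(np.lexsort((q, a_idx, -rs))[0])
    return lo + int(a_idx[k]), lo + int(b_idx[k]), float(rs[k])


def _scan_segment(
    csum: np.ndarray, lo: int, hi: int, n_ranks: int, alpha: float,
    found: list[tuple[int, int, float]],
) -> None:
    """Exhaustive-surprise scan of ranks[lo:hi] (prefix sums in csum).

    Finds the subinterval with maximal RS; if above alpha, records it and
    recurses on the flanking sub-segments.
    """
    best = _segment_max_rs(csum, lo, hi, n_ranks)
    if best is None or best[2] <= alpha:
        return
    i, j, best_rs = best
    found.append((i, j, best_rs))
    _scan_segment(csum, lo, i, n_ranks, alpha, found)
    _scan_segment(csum, j + 1, hi, n_ranks, alpha, found)


def global_rank_surprise(
    trains: dict | list, params: BurstParams = BurstParams()
) -> BurstAnnotation:
    """Detect bursts in every molecule's ISI sequence under global ranking.

    Parameters
    ----------
    trains : dict or list
        Mapping of molecule id to ISI array (seconds), or a list of
        :class:`~kinefp.containers.SpikeTrain` (ISIs computed here).
    params : BurstParams
        Maximal in-burst ISI (s) and RS cutoff.

    Multiplying every ISI (and ``max_isi_in_burst``) by a positive constant
    leaves ranks, RS values and burst labels unchanged.
    """
    if isinstance(trains, dict):
        isis = {m: np.asarray(v, dtype=float) for m, v in trains.items()}
    else:
        isis = {t.molecule_id: compute_isis(t) for t in trains}
    if len(isis) == 0:
        raise ConfigError("need at least one molecule")
    for m, v in isis.items():
        if not np.all(np.isfinite(v)):
            raise ConfigError(f"molecule {m!r} has non-finite ISIs")

    ids = list(isis)
    pooled = np.concatenate([isis[m] for m in ids]) if ids else np.array([])
    n_ranks = pooled.size
    labels = {m: np.full(isis[m].size, "non_burst", dtype=object) for m in ids}
    if n_ranks == 0:
        return BurstAnnotation(bursts=[], isi_labels=labels, isis=isis,
                               params=params)
    ranks = stats.rankdata(pooled, method="average")

    bursts: list[Burst] = []
    offset = 0
    for m in ids:
        v = isis[m]
        r = ranks[offset : offset + v.size]
        offset += v.size
        if v.size == 0:
            continue
        ok = v <= params.max_isi_in_burst
        csum = np.concatenate(([0.0], np.cumsum(r)))
        # maximal runs of consecutive in-threshold ISIs
        edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.view(np.int8), [0]))))
        for lo, hi in zip(edges[::2], edges[1::2]):
            found: list[tuple[int, int, float]] = []
            _scan_segment(csum, int(lo), int(hi), n_ranks, params.alpha, found)
            for i, j, rs in found:
                bursts.append(
                    Burst(
                        molecule_id=m,
                        first_event=i, last_event=j + 1,
                        first_isi=i, last_isi=j, rs=rs,
                    )
                )
                labels[m][i : j + 1] = "burst"
    bursts.sort(key=lambda b: (str(b.molecule_id), b.first_isi))
    return BurstAnnotation(bursts=bursts, isi_labels=labels, isis=isis,
                           params=params)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


@dataclass
class BurstStatistics:
    """Burst vs non-burst ISI distributions and their exponential scales."""

    burst_isis: np.ndarray
    non_burst_isis: np.ndarray
    burst_fit: object | None       # kinetics.ExpFit or None if too few ISIs
    non_burst_fit: object | None
    durations: pd.DataFrame        # per-molecule burst durations (s)

    def summary(self) -> str:
        def scale(fit, arr):
            if fit is not None:
                return f"{fit.tau1:.3g} s (exp fit, n={arr.size})"
            return f"median {np.median(arr):.3g} s (n={arr.size})" if arr.size \
                else "missing"

        return (
            "Burst/non-burst ISI statistics\n"
            f"  burst ISIs:     {scale(self.burst_fit, self.burst_isis)}\n"
            f"  non-burst ISIs: {scale(self.non_burst_fit, self.non_burst_isis)}"
        )


def burst_statistics(annotation: BurstAnnotation) -> BurstStatistics:
    """Pool ISIs by label and fit single-exponential timescales.

    Emits a warning when probe binding is not at least 10x faster than the
    detected burst timescale (timescale separation needed for the bursts to
    reflect a slower conformational process rather than binding noise).
    """
    from .kinetics import fit_exponential_cdf
    from .exceptions import InsufficientDataError

    b = annotation.labelled_isis("burst")
    nb = annotation.labelled_isis("non_burst")

    def _fit(arr):
        try:
            return fit_exponential_cdf(arr, order=1)
        except InsufficientDataError:
            return None

    rows = []
    for burst in annotation.bursts:
        v = annotation.isis[burst.molecule_id]
        rows.append(
            {
                "molecule_id": burst.molecule_id,
                "duration_s": float(v[burst.first_isi : burst.last_isi + 1].sum()),
                "n_isis": burst.n_isis,
                "rs": burst.rs,
            }
        )
    durations = pd.DataFrame(rows)

    if b.size and durations.shape[0]:
        mean_isi = float(b.mean())
        mean_burst = float(durations["duration_s"].mean())
        if mean_burst < 10.0 * mean_isi:
            warnings.warn(
                "probe binding is not >=10x faster than the detected burst "
                f"timescale (mean in-burst ISI {mean_isi:.3g} s vs mean burst "
                f"duration {mean_burst:.3g} s); burst timescales may be "
                "confounded with binding kinetics",
                stacklevel=2,
            )
    return BurstStatistics(
        burst_isis=b, non_burst_isis=nb,
        burst_fit=_fit(b), non_burst_fit=_fit(nb),
        durations=durations,
    )
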