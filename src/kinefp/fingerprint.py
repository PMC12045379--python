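"""Kinetic filtering, threshold optimization and subpopulation analysis.

A trace is counted as a positive detection only if its kinetic fingerprint
(event count, dwell-time medians/maximum, level signal-to-noise, intensity)
satisfies every configured threshold.  Repeated transient binding produces
many events with short bound dwells; nonspecific sticking produces few, long,
irregular events -- so simple box thresholds separate them with very low
false-positive rates, and the thresholds can be optimized on labelled
positive/negative trace sets under an explicit false-positive budget.

Accepted traces can further be classified into transient vs long-lived
kinetic subpopulations with a two-component Gaussian mixture on the log
dwell-time medians, and two-channel experiments summarised as joint
accessibility contingency fractions over colocalized molecules.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InsufficientDataError

__all__ = [
    "FilterThresholds",
    "PopulationAssignment",
    "filter_traces",
    "optimize_thresholds",
    "classify_kinetic_populations",
    "joint_accessibility",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Box thresholds on per-trace fingerprint statistics.

    Every bound is optional (``None`` disables it).  A trace is accepted iff
    all configured bounds hold; statistics that are NaN (e.g. no complete
    dwell) fail any configured bound on that statistic.
    """

    min_n_events: float | None = None
    min_tau_on_median: float | None = None
    max_tau_on_median: float | None = None
    min_tau_off_median: float | None = None
    max_tau_off_median: float | None = None
    max_tau_off_max: float | None = None
    min_snr: float | None = None
    min_bound_level: float | None = None
    max_bound_level: float | None = None

    def __post_init__(self) -> None:
        pairs = [
            ("min_tau_on_median", "max_tau_on_median"),
            ("min_tau_off_median", "max_tau_off_median"),
            ("min_bound_level", "max_bound_level"),
        ]
        for lo, hi in pairs:
            a, b = getattr(self, lo), getattr(self, hi)
            if a is not None and b is not None and a > b:
                raise ConfigError(f"{lo} > {hi}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: (threshold field, statistic column, direction) triples; direction "min"
#: means the statistic must be >= the bound, "max" <=.
_RULES = [
    ("min_n_events", "n_events", "min"),
    ("min_tau_on_median", "tau_on_median", "min"),
    ("max_tau_on_median", "tau_on_median", "max"),
    ("min_tau_off_median", "tau_off_median", "min"),
    ("max_tau_off_median", "tau_off_median", "max"),
    ("max_tau_off_max", "tau_off_max", "max"),
    ("min_snr", "snr", "min"),
    ("min_bound_level", "bound_level", "min"),
    ("max_bound_level", "bound_level", "max"),
]


def _as_frame(stats) -> pd.DataFrame:
    if isinstance(stats, pd.DataFrame):
        return stats
    from .idealize import stats_frame

    return stats_frame(list(stats))


def filter_traces(stats, thresholds: FilterThresholds) -> tuple[pd.Series, int]:
    """Apply thresholds; returns (boolean accept flags, N_accepted)."""
    df = _as_frame(stats)
    ok = pd.Series(True, index=df.index)
    for name, col, direction in _RULES:
        bound = getattr(thresholds, name)
        if bound is None:
            continue
        v = df[col]
        cond = (v >= bound) if direction == "min" else (v <= bound)
        ok &= cond.fillna(False)
    return ok, int(ok.sum())


# candidate-grid construction for the optimizer ------------------------------

#: dimensions searched by optimize_thresholds, in strictness tie-break order
_OPT_DIMS = [
    ("min_n_events", "n_events", "min"),
    ("max_tau_off_max", "tau_off_max", "max"),
    ("min_snr", "snr", "min"),
    ("max_tau_on_median", "tau_on_median", "max"),
    ("min_tau_on_median", "tau_on_median", "min"),
    ("max_tau_off_median", "tau_off_median", "max"),
]

_QUANTS = (0.02, 0.25, 0.5, 0.75, 0.98)


def optimize_thresholds(
    positive_stats,
    negative_stats,
    fp_budget: float = 2.0,
) -> FilterThresholds:
    """Grid-search thresholds maximizing accepted positives s.t. FP <= budget.

    Candidate values per dimension are quantiles of the pooled statistics
    (plus "no bound"); all combinations are scored on the labelled sets.
    Ties are broken deterministically in favour of stricter thresholds
    (lexicographically over the dimension order, strictest first).

    ``fp_budget`` is the tolerated number of accepted negatives in the
    supplied negative set (one field-of-view-equivalent).
    """
    pos = _as_frame(positive_stats)
    neg = _as_frame(negative_stats)
    if len(pos) == 0:
        raise InsufficientDataError("positive set is empty")
    if len(neg) == 0:
        raise InsufficientDataError("negative set is empty")

    pooled = pd.concat([pos, neg], ignore_index=True)
    cand: list[list[float | None]] = []
    masks_pos: list[list[np.ndarray]] = []
    masks_neg: list[list[np.ndarray]] = []
    for name, col, direction in _OPT_DIMS:
        vals = pooled[col].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            levels: list[float | None] = [None]
        else:
            qs = np.unique(np.quantile(vals, _QUANTS))
            # order from least to most strict so that a larger candidate
            # index always means a stricter bound
            levels = [None] + list(qs if direction == "min" else qs[::-1])
        cand.append(levels)
        mp, mn = [], []
        for lev in levels:
            if lev is None:
                mp.append(np.ones(len(pos), dtype=bool))
                mn.append(np.ones(len(neg), dtype=bool))
            else:
                for df, acc in ((pos, mp), (neg, mn)):
                    v = df[col].to_numpy(dtype=float)
                    good = np.isfinite(v)
                    ok = (v >= lev) if direction == "min" else (v <= lev)
                    acc.append(ok & good)
        masks_pos.append(mp)
        masks_neg.append(mn)

    best_tp = -1
    best_key: tuple | None = None
    best_combo: tuple[int, ...] | None = None
    for combo in itertools.product(*(range(len(c)) for c in cand)):
        mp = masks_pos[0][combo[0]].copy()
        mn = masks_neg[0][combo[0]].copy()
        for dim in range(1, len(combo)):
            mp &= masks_pos[dim][combo[dim]]
            mn &= masks_neg[dim][combo[dim]]
        fp = int(mn.sum())
        if fp > fp_budget:
            continue
        tp = int(mp.sum())
        key = (tp, combo)  # higher candidate index = stricter
        if tp > best_tp or (tp == best_tp and key > best_key):
            best_tp, best_key, best_combo = tp, key, combo
    if best_combo is None:
        # even the strictest grid point exceeds the budget; reject everything
        return FilterThresholds(min_n_events=math.inf)
    kwargs = {
        name: cand[d][best_combo[d]]
        for d, (name, _, _) in enumerate(_OPT_DIMS)
    }
    return FilterThresholds(**kwargs)


# kinetic subpopulations -----------------------------------------------------


@dataclass
class PopulationAssignment:
    """Mixture classification of accepted traces into kinetic clusters."""

    labels: np.ndarray            # "transient" / "long_lived" per trace
    fractions: dict               # label -> fraction of accepted traces
    fraction_se: dict             # binomial standard errors
    n_components: int
    means: np.ndarray             # component means in (log tau_on, log tau_off)
    bic: dict                     # n_components -> BIC

    def summary(self) -> str:
        lines = [f"Kinetic population mixture ({self.n_components} component(s))"]
        for lab in sorted(self.fractions):
            lines.append(
                f"  {lab}: {100 * self.fractions[lab]:.1f}% "
                f"(+/- {100 * self.fraction_se[lab]:.1f}%)"
            )
        return "\n".join(lines)


def classify_kinetic_populations(
    accepted_stats, min_traces: int = 20, random_state: int = 0
) -> PopulationAssignment:
    """Two-component Gaussian mixture on (log tau_on_median, log tau_off_median).

    Initialization is deterministic: component means start at the 25th/75th
    percentile corner points of the feature cloud.  One component is chosen
    when BIC prefers it; with two components, ``transient`` is the one with
    the smaller mean log bound-state dwell.
    """
    from sklearn.mixture import GaussianMixture

    df = _as_frame(accepted_stats)
    X = np.log(df[["tau_on_median", "tau_off_median"]].to_numpy(dtype=float))
    good = np.all(np.isfinite(X), axis=1)
    X = X[good]
    if X.shape[0] < min_traces:
        raise InsufficientDataError(
            f"need >= {min_traces} accepted traces, got {X.shape[0]}"
        )

    q25, q75 = np.quantile(X, [0.25, 0.75], axis=0)
    gm2 = GaussianMixture(
        n_components=2, covariance_type="full", n_init=1,
        means_init=np.vstack([q25, q75]), random_state=random_state,
    ).fit(X)
    gm1 = GaussianMixture(n_components=1, random_state=random_state).fit(X)
    bic = {1: float(gm1.bic(X)), 2: float(gm2.bic(X))}

    labels = np.full(len(df), "rejected", dtype=object)
    if bic[1] <= bic[2]:
        labels[good] = "transient"
        fractions = {"transient": 1.0}
        se = {"transient": 0.0}
        return PopulationAssignment(
            labels=labels, fractions=fractions, fraction_se=se,
            n_components=1, means=gm1.means_, bic=bic,
        )
    comp = gm2.predict(X)
    transient_idx = int(np.argmin(gm2.means_[:, 0]))
    name = np.where(comp == transient_idx, "transient", "long_lived")
    labels[good] = name
    n = comp.size
    fractions, se = {}, {}
    for lab in ("transient", "long_lived"):
        f = float((name == lab).mean())
        fractions[lab] = f
        se[lab] = math.sqrt(f * (1 - f) / n)
    return PopulationAssignment(
        labels=labels, fractions=fractions, fraction_se=se,
        n_components=2, means=gm2.means_, bic=bic,
    )


# two-channel joint accessibility --------------------------------------------


def joint_accessibility(
    matches: list[tuple[int, int, float]],
    accept_a,
    accept_b,
    labels_b=None,
    n_rois_a: int | None = None,
    n_rois_b: int | None = None,
) -> dict:
    """Contingency fractions of molecules by per-channel acceptance.

    A molecule is a colocalized ROI pair or an unmatched ROI in either
    channel.  Returns fractions of molecules accepted in channel A only,
    B only, both, or neither, plus -- when per-trace ``labels_b`` are given
    -- the fraction of each B label that shows any A acceptance.
    """
    accept_a = np.asarray(accept_a, dtype=bool)
    accept_b = np.asarray(accept_b, dtype=bool)
    n_rois_a = accept_a.size if n_rois_a is None else n_rois_a
    n_rois_b = accept_b.size if n_rois_b is None else n_rois_b
    matched_a = {i for i, _, _ in matches}
    matched_b = {j for _, j, _ in matches}

    rows = []
    for i, j, _ in matches:
        rows.append((bool(accept_a[i]), bool(accept_b[j]), j))
    for i in range(n_rois_a):
        if i not in matched_a:
            rows.append((bool(accept_a[i]), False, None))
    for j in range(n_rois_b):
        if j not in matched_b:
            rows.append((False, bool(accept_b[j]), j))

    n = len(rows)
    counts = {"both": 0, "a_only": 0, "b_only": 0, "neither": 0}
    for a_ok, b_ok, _ in rows:
        if a_ok and b_ok:
            counts["both"] += 1
        elif a_ok:
            counts["a_only"] += 1
        elif b_ok:
            counts["b_only"] += 1
        else:
            counts["neither"] += 1
    out = {k: (v / n if n else np.nan) for k, v in counts.items()}
    out["n_molecules"] = n

    if labels_b is not None:
        labels_b = np.asarray(labels_b, dtype=object)
        by_label: dict[str, float] = {}
        for lab in np.unique(labels_b):
            idx = [r for r in rows if r[2] is not None
                   and r[1] and labels_b[r[2]] == lab]
            if idx:
                by_label[str(lab)] = float(np.mean([r[0] for r in idx]))
        out["a_given_b_label"] = by_label
    return out
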