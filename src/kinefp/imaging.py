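"""Spot detection and trace extraction from image stacks.

Candidate binding sites are found on an intensity *fluctuation map* -- the
mean absolute frame-to-frame intensity change per pixel -- which highlights
pixels whose brightness blinks as probes bind and dissociate, while constant
background (bright or dark) stays near the noise floor.  ROIs are the 3x3
windows centered on local maxima of the map; traces are the integrated,
background-subtracted window intensities, with the local background taken as
the median of the 16-pixel ring of the surrounding 5x5 neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .containers import IntensityTrace, MovieStack
from .exceptions import ConfigError

__all__ = [
    "FluctuationMap",
    "ROI",
    "compute_fluctuation_map",
    "detect_rois",
    "detection_threshold",
    "extract_trace",
    "colocalize_rois",
]

#: half-width of the background ring neighbourhood; ROI centers must be at
#: least this far from every border so the 5x5 ring fits.
BORDER_MARGIN = 2


@dataclass
class FluctuationMap:
    """Mean absolute frame-to-frame intensity change per pixel."""

    data: np.ndarray
    exposure: float
    channel: str = "ch0"

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class ROI:
    """A 3x3 detection window centered on (row, col), 0-based."""

    row: int
    col: int
    peak: float = np.nan
    channel: str = "ch0"

    @property
    def center(self) -> tuple[int, int]:
        return (self.row, self.col)


def compute_fluctuation_map(movie: MovieStack) -> FluctuationMap:
    """map[p] = mean over t of ``|I(t+1, p) - I(t, p)|``.

    Requires at least two frames.  Depends only on successive frame
    differences, so it is exactly recomputable from any movie with the same
    difference sequence.
    """
    if movie.n_frames < 2:
        raise ConfigError("fluctuation map needs at least 2 frames")
    diffs = np.abs(np.diff(movie.data.astype(np.float64), axis=0))
    return FluctuationMap(
        data=diffs.mean(axis=0), exposure=movie.exposure, channel=movie.channel
    )


def detection_threshold(fmap: FluctuationMap, n_sigma: float = 4.0) -> float:
    """Default threshold policy: map mean + n_sigma x robust (MAD-based) sd."""
    m = fmap.data
    med = np.median(m)
    mad = np.median(np.abs(m - med))
    return float(m.mean() + n_sigma * 1.4826 * mad)


def detect_rois(
    fmap: FluctuationMap,
    min_separation: float = 3.0,
    threshold: float | None = None,
    channel: str | None = None,
) -> list[ROI]:
    """Local maxima of the fluctuation map above threshold, with suppression.

    Candidates are interior pixels (>= 2 px from every border so the 5x5
    background ring fits) that are >= all 8 neighbours and strictly above the
    threshold (default: :func:`detection_threshold`).  Candidates are ordered
    by descending peak value (ties broken row-major) and greedily accepted
    unless within ``min_separation`` (Euclidean, px) of an accepted peak.
    The returned list keeps that deterministic ordering.
    """
    m = fmap.data
    thr = detection_threshold(fmap) if threshold is None else threshold
    is_max = m >= ndimage.maximum_filter(m, size=3, mode="nearest")
    is_max &= m > thr
    is_max[:BORDER_MARGIN, :] = False
    is_max[-BORDER_MARGIN:, :] = False
    is_max[:, :BORDER_MARGIN] = False
    is_max[:, -BORDER_MARGIN:] = False
    rows, cols = np.nonzero(is_max)
    if rows.size == 0:
        return []
    order = np.lexsort((cols, rows, -m[rows, cols]))
    accepted: list[ROI] = []
    kept = np.empty((0, 2))
    ch = fmap.channel if channel is None else channel
    for i in order:
        p = np.array([[rows[i], cols[i]]], dtype=float)
        if kept.size and (((kept - p) ** 2).sum(axis=1) < min_separation**2).any():
            continue
        kept = np.vstack((kept, p))
        accepted.append(
            ROI(row=int(rows[i]), col=int(cols[i]), peak=float(m[rows[i], cols[i]]),
                channel=ch)
        )
    return accepted


def extract_trace(movie: MovieStack, roi: ROI) -> IntensityTrace:
    """Integrated, background-subtracted 3x3 window intensity per frame.

    Background is estimated per frame as the median of the 16-pixel ring of
    the surrounding 5x5 neighbourhood (robust to bleed-through from
    neighbouring spots), scaled by the 9 window pixels:
    ``trace[t] = sum(window) - 9 * median(ring)``.
    """
    nr, nc = movie.frame_shape
    r, c = roi.row, roi.col
    if not (BORDER_MARGIN <= r < nr - BORDER_MARGIN
            and BORDER_MARGIN <= c < nc - BORDER_MARGIN):
        raise ConfigError(f"ROI ({r}, {c}) too close to the border for a 5x5 ring")
    if roi.channel != movie.channel:
        raise ConfigError(
            f"ROI channel {roi.channel!r} does not match movie channel "
            f"{movie.channel!r}"
        )
    block = movie.data[:, r - 2 : r + 3, c - 2 : c + 3].astype(np.float64)
    window = block[:, 1:4, 1:4].sum(axis=(1, 2))
    ring = block.reshape(movie.n_frames, 25)
    inner = [6, 7, 8, 11, 12, 13, 16, 17, 18]
    ring = np.delete(ring, inner, axis=1)
    background = np.median(ring, axis=1)
    return IntensityTrace(
        intensity=window - 9.0 * background,
        exposure=movie.exposure,
        roi=(r, c),
        channel=movie.channel,
    )


def colocalize_rois(
    a: list[ROI], b: list[ROI], radius: float
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Greedy one-to-one nearest-neighbour matching between two channels.

    Pairs are considered in order of increasing distance (ties by index);
    each ROI is matched at most once and only within ``radius`` pixels.
    Returns ``(matches, unmatched_a, unmatched_b)`` where matches are
    ``(index_in_a, index_in_b, distance)``.
    """
    if radius < 0:
        raise ConfigError("radius must be >= 0")
    if not a or not b:
        return [], list(range(len(a))), list(range(len(b)))
    pa = np.array([r.center for r in a], dtype=float)
    pb = np.array([r.center for r in b], dtype=float)
    d = cdist(pa, pb)
    ii, jj = np.nonzero(d <= radius)
    order = np.lexsort((jj, ii, d[ii, jj]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j, float(d[i, j])))
    unmatched_a = [i for i in range(len(a)) if i not in used_a]
    unmatched_b = [j for j in range(len(b)) if j not in used_b]
    return matches, unmatched_a, unmatched_b
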