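"""Shared data containers: movies, intensity traces, event trains, ground truth.

These are thin, validated wrappers over numpy arrays.  Everything downstream
(idealization, kinetics, bursting, Fano statistics) consumes these types, and
the synthetic generator produces them, so simulated and file-loaded data take
identical code paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError

__all__ = ["MovieStack", "IntensityTrace", "SpikeTrain", "GroundTruth"]


@dataclass
class MovieStack:
    """A single-channel image stack (frames x rows x cols).

    Parameters
    ----------
    data : ndarray, shape (n_frames, rows, cols)
        Pixel intensities in camera counts.
    exposure : float
        Frame exposure time in seconds.
    pixel_size : float, optional
        Pixel edge length in micrometres (metadata only).
    channel : str
        Channel label, e.g. ``"Cy5"``.
    """

    data: np.ndarray
    exposure: float
    pixel_size: float = 1.0
    channel: str = "ch0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigError("movie data must be 3-D (frames, rows, cols)")
        if self.exposure <= 0:
            raise ConfigError("exposure must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def duration(self) -> float:
        """Total movie duration in seconds (n_frames x exposure)."""
        return self.n_frames * self.exposure


@dataclass
class IntensityTrace:
    """Background-subtracted intensity versus time for one molecule/ROI."""

    intensity: np.ndarray
    exposure: float
    roi: tuple[int, int] | None = None
    channel: str = "ch0"
    trace_id: int | str | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 1:
            raise ConfigError("trace intensity must be 1-D")
        if self.exposure <= 0:
            raise ConfigError("exposure must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.size

    @property
    def time(self) -> np.ndarray:
        """Time grid in seconds: frame_index x exposure."""
        return np.arange(self.n_frames) * self.exposure

    @property
    def duration(self) -> float:
        return self.n_frames * self.exposure


@dataclass
class SpikeTrain:
    """Ordered binding-event intervals for one molecule.

    Events are intervals ``[onset, end]`` in seconds; point events (e.g. a
    Poisson process) have ``end == onset``.  Inter-spike intervals are gaps
    between consecutive events (end of one to onset of the next), which for
    a two-state trace equal the complete unbound dwell times.
    """

    onsets: np.ndarray
    ends: np.ndarray
    duration: float
    molecule_id: int | str = 0

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if self.onsets.shape != self.ends.shape or self.onsets.ndim != 1:
            raise ConfigError("onsets/ends must be matching 1-D arrays")
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if np.any(self.ends < self.onsets):
            raise ConfigError("event end precedes its onset")
        if self.onsets.size > 1:
            if np.any(np.diff(self.onsets) < 0) or np.any(
                self.onsets[1:] < self.ends[:-1]
            ):
                raise ConfigError("events must be sorted and disjoint")

    @classmethod
    def from_times(
        cls, times, duration: float, molecule_id: int | str = 0
    ) -> "SpikeTrain":
        """Build a point-event train from sorted event times."""
        t = np.sort(np.asarray(times, dtype=float))
        return cls(onsets=t, ends=t.copy(), duration=duration, molecule_id=molecule_id)

    @property
    def n_events(self) -> int:
        return self.onsets.size


@dataclass
class GroundTruth:
    """Per-frame hidden state and event bookkeeping for a simulated trace.

    Attributes
    ----------
    states : ndarray of int8
        1 = probe bound, 0 = unbound, per frame.
    exposure : float
        Seconds per frame.
    params : dict
        Echo of the generating configuration.
    conformation : ndarray of int8, optional
        Slow accessibility layer for modulated simulations
        (1 = accessible, 0 = blocked).
    """

    states: np.ndarray
    exposure: float
    params: dict = field(default_factory=dict)
    conformation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)

    @property
    def n_frames(self) -> int:
        return self.states.size

    def bound_intervals(self) -> np.ndarray:
        """Disjoint, ordered (start_s, end_s) intervals of the bound state.

        Intervals lie within ``[0, n_frames * exposure]``; a run of frames
        ``i..j`` (inclusive) maps to ``[i * exposure, (j + 1) * exposure]``.
        """
        s = self.states
        if s.size == 0:
            return np.empty((0, 2))
        changes = np.flatnonzero(np.diff(s) != 0) + 1
        starts = np.concatenate(([0], changes))
        ends = np.concatenate((changes, [s.size]))
        mask = s[starts] == 1
        out = np.column_stack((starts[mask], ends[mask])).astype(float)
        return out * self.exposure

    def spike_train(self, molecule_id: int | str = 0) -> SpikeTrain:
        """Binding events as a :class:`SpikeTrain` (onset/end of bound runs)."""
        iv = self.bound_intervals()
        return SpikeTrain(
            onsets=iv[:, 0],
            ends=iv[:, 1],
            duration=self.n_frames * self.exposure,
            molecule_id=molecule_id,
        )
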