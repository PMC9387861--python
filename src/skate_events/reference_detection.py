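"""Marker-based (reference-system) detection of ground-contact events.

Vertical marker trajectories of the pole tips and skis are segmented into
ground-contact runs by a proximity threshold, and the contact (ON) and
release (OFF) instants are placed at the maxima of the second derivative of
the vertical position in short windows around each run boundary — the
vertical deceleration peaks when a pole tip or ski wheel meets or leaves the
treadmill belt.

This module also owns the :class:`Event` / :class:`EventSeries` containers
used by every detector in the package.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np

from skate_events.errors import InvalidParameterError
from skate_events.signal_core import (
    MarkerTrack, UniformSeries, butter_filter, second_derivative,
)

__all__ = [
    "Event", "EventSeries", "ProximityMask",
    "ground_proximity", "detect_reference_events",
    "EVENT_TYPES", "family_of",
]

log = logging.getLogger(__name__)

EVENT_TYPES = ("P_ON", "P_OFF", "S_ON", "S_OFF")
SIDES = ("left", "right", "merged")
SOURCES = ("reference", "imu", "ground_truth")

#: Minimum separation between two events of identical (etype, side), seconds.
DEFAULT_REFRACTORY_S = 0.050


def family_of(etype: str) -> str:
    """'pole' for P_* events, 'ski' for S_* events."""
    return "pole" if etype.startswith("P") else "ski"


@dataclass(frozen=True, order=True)
class Event:
    """One typed, sided, time-stamped ground-contact event."""

    time: float
    etype: str
    side: str
    source: str = "reference"

    def __post_init__(self):
        if self.etype not in EVENT_TYPES:
            raise InvalidParameterError(f"unknown event type {self.etype!r}")
        if self.side not in SIDES:
            raise InvalidParameterError(f"unknown side {self.side!r}")
        if self.source not in SOURCES:
            raise InvalidParameterError(f"unknown source {self.source!r}")

    @property
    def family(self) -> str:
        return family_of(self.etype)

    def is_on(self) -> bool:
        return self.etype.endswith("_ON")

    def shifted(self, dt: float) -> "Event":
        return replace(self, time=self.time + dt)


@dataclass
class EventSeries:
    """Time-ordered events of one trial.

    For each (event family, side) the ON and OFF events must strictly
    alternate in time (starting with either), and no two events of identical
    (etype, side) may fall within the physical refractory bound.
    """

    events: list[Event] = field(default_factory=list)
    trial_id: str = ""
    refractory_s: float = DEFAULT_REFRACTORY_S

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: e.time)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def validate(self) -> "EventSeries":
        """Raise InvalidParameterError on an alternation or refractory
        violation; return self when valid."""
        keys = {(e.family, e.side) for e in self.events}
        for fam, side in keys:
            sub = [e for e in self.events if e.family == fam and e.side == side]
            for a, b in zip(sub, sub[1:]):
                if a.is_on() == b.is_on():
                    raise InvalidParameterError(
                        f"alternation violated for ({fam}, {side}) at "
                        f"t={a.time:.3f}/{b.time:.3f}")
            for et in {e.etype for e in sub}:
                ts = [e.time for e in sub if e.etype == et]
                for t1, t2 in zip(ts, ts[1:]):
                    if t2 - t1 < self.refractory_s:
                        raise InvalidParameterError(
                            f"refractory violated for ({et}, {side}): "
                            f"{t1:.3f} -> {t2:.3f}")
        return self

    def select(self, etype: str | None = None, side: str | None = None,
               family: str | None = None) -> "EventSeries":
        evs = [e for e in self.events
               if (etype is None or e.etype == etype)
               and (side is None or e.side == side)
               and (family is None or e.family == family)]
        return EventSeries(evs, trial_id=self.trial_id,
                           refractory_s=self.refractory_s)

    def times(self, etype: str | None = None, side: str | None = None) -> np.ndarray:
        return np.array([e.time for e in self.select(etype, side)], dtype=float)

    def shifted(self, dt: float) -> "EventSeries":
        return EventSeries([e.shifted(dt) for e in self.events],
                           trial_id=self.trial_id, refractory_s=self.refractory_s)

    def merged_with(self, other: Iterable[Event]) -> "EventSeries":
        return EventSeries(self.events + list(other), trial_id=self.trial_id,
                           refractory_s=self.refractory_s)


@dataclass(frozen=True)
class ProximityMask:
    """Boolean ground-proximity mask aligned to a MarkerTrack."""

    mask: np.ndarray
    threshold_m: float

    def __post_init__(self):
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    def __len__(self) -> int:
        return self.mask.size

    def runs(self) -> list[tuple[int, int]]:
        """Contiguous true-runs as (start, stop) index pairs, stop exclusive."""
        m = self.mask
        if not m.any():
            return []
        padded = np.concatenate(([False], m, [False])).astype(int)
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        stops = np.flatnonzero(d == -1)
        return list(zip(starts.tolist(), stops.tolist()))


def ground_proximity(track: MarkerTrack, quantile: float = 0.1,
                     margin_m: float = 0.003,
                     min_run_s: float = 0.025) -> ProximityMask:
    """Mask where the marker is close to the treadmill surface.

    True where ``z <= quantile(z) + margin_m`` — the treadmill height is
    constant within a trial, so the lower quantile of the vertical trajectory
    tracks the belt level.  The margin is kept small (a few noise standard
    deviations): a generous margin puts the threshold crossing far up the
    flight arc, outside the curvature-search window at the run boundary.
    False gaps and true runs shorter than ``min_run_s`` are closed/removed
    as noise.  A constant trajectory yields an all-true mask with a warning
    (degenerate trial).
    """
    if not (0.0 < quantile < 0.5):
        raise InvalidParameterError("quantile must lie in (0, 0.5)")
    z = track.z.values
    if np.ptp(z) < 1e-12:
        log.warning("constant vertical trajectory for %s: all-true mask",
                    track.location)
        warnings.warn("constant vertical trajectory: degenerate all-true mask",
                      stacklevel=2)
        return ProximityMask(np.ones_like(z, dtype=bool), float(z[0]))
    thr = float(np.quantile(z, quantile) + margin_m)
    mask = z <= thr
    min_run = int(round(min_run_s * track.z.fs))
    if min_run > 1:
        # close single-sample noise gaps inside contacts first, then drop
        # spurious short contacts
        inv = ProximityMask(~mask, thr)
        for i0, i1 in inv.runs():
            if i1 - i0 < min_run and i0 > 0 and i1 < mask.size:
                mask[i0:i1] = True
        pm = ProximityMask(mask, thr)
        for i0, i1 in pm.runs():
            if i1 - i0 < min_run:
                mask[i0:i1] = False
    return ProximityMask(mask, thr)


def detect_reference_events(track: MarkerTrack, mask: ProximityMask,
                            family: Literal["pole", "ski"] | None = None,
                            side: str | None = None,
                            window_s: float = 0.05,
                            smooth_hz: float | None = 20.0,
                            smooth_order: int = 2,
                            trial_id: str = "") -> EventSeries:
    """Contact/release events from curvature maxima at run boundaries.

    For each contiguous ground-proximity run, the ON event is the time of
    the maximum of the second derivative of the (optionally low-passed)
    vertical position within ``±window_s`` of the run start, and the OFF
    event the analogous maximum around the run end.  Runs at the trial
    boundary that lack a complete window emit no event there.  Timestamps
    stay on the marker sampling grid (no sub-sample interpolation).

    ``smooth_hz`` low-passes z before differentiating; the second difference
    at 200 Hz amplifies millimetre-level marker noise by fs², so a wideband
    (default 20 Hz, zero-phase) pre-smoothing is applied.  Set to ``None``
    to differentiate the raw trajectory.
    """
    if len(mask) != len(track.z):
        raise InvalidParameterError("mask must be aligned to the track")
    fam = family or track.family
    sd = side or track.side
    z = track.z
    if smooth_hz is not None:
        z = butter_filter(z, smooth_order, smooth_hz, "lowpass")
    curv = second_derivative(z).values
    w = int(round(window_s * z.fs))
    n = len(curv)
    on_t, off_t = ("P_ON", "P_OFF") if fam == "pole" else ("S_ON", "S_OFF")

    events: list[Event] = []
    for i0, i1 in mask.runs():
        i_end = i1 - 1  # last sample of the run
        on_idx = off_idx = None
        if i0 - w >= 0 and i0 + w < n:
            lo, hi = i0 - w, i0 + w + 1
            on_idx = lo + int(np.argmax(curv[lo:hi]))
        if i_end - w >= 0 and i_end + w < n:
            lo, hi = i_end - w, i_end + w + 1
            off_idx = lo + int(np.argmax(curv[lo:hi]))
        if on_idx is not None and off_idx is not None and on_idx >= off_idx:
            # degenerate short run: keep the stronger boundary only
            if curv[on_idx] >= curv[off_idx]:
                off_idx = None
            else:
                on_idx = None
        if on_idx is not None:
            events.append(Event(z.time_at(on_idx), on_t, sd, "reference"))
        if off_idx is not None:
            events.append(Event(z.time_at(off_idx), off_t, sd, "reference"))
    return EventSeries(events, trial_id=trial_id).validate()
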