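"""IMU-based detection of pole and ski ground-contact events.

Wrist pipeline (per wrist):

* the yaw-axis angular velocity is integrated and high-passed (2nd order,
  0.1 Hz, zero-phase) to obtain a drift-free yaw angle; its prominent local
  maxima anchor the arm cycles;
* P_ON — from each yaw-angle maximum, scan forward for the first positive
  yaw-acceleration peak with prominence >= 1 m·s⁻²; P_ON is the last
  negative acceleration peak strictly before it (no earlier than the anchor);
* P_OFF — the yaw acceleration is high-passed at 5 Hz to isolate the sharp
  pole-release transient; P_OFF is the most-negative peak of the filtered
  signal near the yaw-angle minimum of the cycle.

Ski pipeline (per ski):

* the roll angular velocity low-passed at 2 Hz gives the leg-cycle
  frequency; cycles are anchored at its positive-going zero crossings;
* S_ON — coarse time at the maximum of the drift-removed integrated roll
  angle, refined to the maximal raw vertical-axis acceleration peak nearby;
* S_OFF — the roll-angle minimum in the final portion of the cycle, refined
  to the most-negative raw vertical acceleration peak nearby.

A cycle whose constituent peaks are absent yields a miss, never an
extrapolated event: missing is a first-class outcome of the method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from skate_events.errors import InsufficientCyclesError, InvalidParameterError
from skate_events.reference_detection import Event, EventSeries
from skate_events.signal_core import (
    IMURecording, UniformSeries, butter_filter, find_peaks, integrate_signal,
)

__all__ = [
    "DetectionConfig", "CycleSegmentation", "DetectionResult",
    "segment_wrist_cycles", "segment_ski_cycles",
    "detect_pole_on", "detect_pole_off", "detect_ski_on", "detect_ski_off",
    "detect_wrist_events", "detect_ski_events", "enforce_alternation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Tunable constants of the IMU event detectors.

    Filter cutoffs and the acceleration-prominence gate follow the method's
    published constants; the search windows (``near_window_s``, the anchor
    spacing band, the cycle tail fraction) are implementation choices, kept
    below half the shortest phase duration at the fastest protocol speeds.
    """

    hp_drift_hz: float = 0.1          # removes integration drift from angles
    hp_poleoff_hz: float = 5.0        # isolates the pole-release transient
    lp_ski_hz: float = 2.0            # leg-cycle band of the roll rate
    min_prominence_acc: float = 1.0   # m·s⁻², acceleration peak gate
    near_window_s: float = 0.15       # s, half-width of refinement windows
    filter_order: int = 2
    anchor_prominence_deg: float = 5.0
    min_anchor_spacing_s: float = 0.4
    max_anchor_spacing_s: float = 4.0
    ski_off_tail_frac: float = 0.4    # final portion of the cycle searched

    def __post_init__(self):
        if self.near_window_s <= 0:
            raise InvalidParameterError("near_window_s must be > 0")
        if not (0 < self.ski_off_tail_frac <= 1):
            raise InvalidParameterError("ski_off_tail_frac must be in (0, 1]")


@dataclass(frozen=True)
class CycleSegmentation:
    """Ordered per-limb cycle anchors (times, seconds)."""

    anchors: np.ndarray
    source_limb: str

    def __post_init__(self):
        a = np.asarray(self.anchors, dtype=float)
        if a.size > 1 and not np.all(np.diff(a) > 0):
            raise InvalidParameterError("anchors must be strictly increasing")
        object.__setattr__(self, "anchors", a)

    def __len__(self) -> int:
        return self.anchors.size

    def cycles(self):
        """Consecutive (start, end) anchor pairs."""
        return zip(self.anchors[:-1], self.anchors[1:])


@dataclass
class DetectionResult:
    """Events found by one detector plus its miss accounting."""

    events: EventSeries
    n_cycles: int = 0
    n_missed: int = 0


def _enforce_spacing(times: np.ndarray, scores: np.ndarray,
                     cfg: DetectionConfig) -> np.ndarray:
    """Drop the lesser-score member of anchor pairs closer than the minimum
    spacing; warn about implausibly long gaps."""
    times = list(times)
    scores = list(scores)
    i = 0
    while i < len(times) - 1:
        if times[i + 1] - times[i] < cfg.min_anchor_spacing_s:
            drop = i if scores[i] <= scores[i + 1] else i + 1
            del times[drop], scores[drop]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.asarray(times)
    if out.size > 1 and np.any(np.diff(out) > cfg.max_anchor_spacing_s):
        log.warning("anchor spacing above %.1f s: possible dropped cycles",
                    cfg.max_anchor_spacing_s)
    return out


def _drift_free_angle(gyro: UniformSeries, cfg: DetectionConfig) -> UniformSeries:
    angle = integrate_signal(gyro)
    return butter_filter(angle, cfg.filter_order, cfg.hp_drift_hz, "highpass")


def segment_wrist_cycles(rec: IMURecording,
                         cfg: DetectionConfig = DetectionConfig()) -> CycleSegmentation:
    """Arm-cycle anchors at the prominent maxima of the drift-free wrist
    yaw angle.

    Raises :class:`InsufficientCyclesError` when fewer than two anchors are
    found (e.g. a motionless recording).
    """
    if not rec.is_wrist():
        raise InvalidParameterError(f"{rec.location!r} is not a wrist recording")
    angle = _drift_free_angle(rec.gyro_axis("yaw"), cfg)
    peaks = find_peaks(angle, cfg.anchor_prominence_deg, "positive")
    times = angle.t0 + peaks.indices / angle.fs
    anchors = _enforce_spacing(times, peaks.prominences, cfg)
    if anchors.size < 2:
        raise InsufficientCyclesError(int(anchors.size))
    return CycleSegmentation(anchors, rec.location)


def segment_ski_cycles(rec: IMURecording,
                       cfg: DetectionConfig = DetectionConfig()) -> CycleSegmentation:
    """Leg-cycle anchors at positive-going zero crossings of the 2 Hz
    low-passed roll angular velocity."""
    if not rec.is_ski():
        raise InvalidParameterError(f"{rec.location!r} is not a ski recording")
    lp = butter_filter(rec.gyro_axis("roll"), cfg.filter_order, cfg.lp_ski_hz,
                       "lowpass")
    v = lp.values
    up = np.flatnonzero((v[:-1] < 0) & (v[1:] >= 0)) + 1
    # hysteresis: a crossing counts only if the rate visited a genuinely
    # negative lobe since the previous crossing (rejects edge/noise wiggles)
    arm_level = -0.2 * np.max(np.abs(v)) if v.size else 0.0
    armed_up = []
    prev = 0
    for i in up:
        if np.min(v[prev:i]) < arm_level:
            armed_up.append(i)
        prev = i
    up = np.asarray(armed_up, dtype=int)
    times = lp.t0 + up / lp.fs
    # score crossings by the local slope so spacing conflicts keep the
    # stronger (steeper, less noise-prone) crossing
    slopes = v[up] - v[up - 1]
    anchors = _enforce_spacing(times, slopes, cfg)
    if anchors.size < 2:
        raise InsufficientCyclesError(int(anchors.size))
    return CycleSegmentation(anchors, rec.location)


def _peaks_in(peaks_idx: np.ndarray, series: UniformSeries,
              t_lo: float, t_hi: float) -> np.ndarray:
    """Subset of peak indices whose times fall inside [t_lo, t_hi]."""
    t = series.t0 + peaks_idx / series.fs
    return peaks_idx[(t >= t_lo) & (t <= t_hi)]


def detect_pole_on(rec: IMURecording, seg: CycleSegmentation,
                   cfg: DetectionConfig = DetectionConfig()) -> DetectionResult:
    """P_ON per arm cycle: the last negative yaw-acceleration peak before the
    first prominent positive peak after the yaw-angle maximum."""
    acc = rec.acc_axis("yaw")
    pos = find_peaks(acc, cfg.min_prominence_acc, "positive").indices
    neg = find_peaks(acc, cfg.min_prominence_acc, "negative").indices
    events: list[Event] = []
    missed = 0
    n_cyc = 0
    for a0, a1 in seg.cycles():
        n_cyc += 1
        p = _peaks_in(pos, acc, a0, a1)
        # first positive peak that is actually preceded (since the anchor)
        # by a negative peak; a bare positive peak right at the anchor has
        # no deceleration apex before it and cannot mark a plant
        found = None
        for first_pos in p:
            nn = neg[neg < first_pos]
            nn = _peaks_in(nn, acc, a0, acc.time_at(int(first_pos)))
            if nn.size:
                found = int(nn[-1])
                break
        if found is None:
            missed += 1
            continue
        events.append(Event(acc.time_at(found), "P_ON", rec.side, "imu"))
    return DetectionResult(EventSeries(events), n_cycles=n_cyc, n_missed=missed)


def detect_pole_off(rec: IMURecording, seg: CycleSegmentation,
                    cfg: DetectionConfig = DetectionConfig()) -> DetectionResult:
    """P_OFF per arm cycle: the most-negative peak of the 5 Hz high-passed
    yaw acceleration near the yaw-angle minimum."""
    angle = _drift_free_angle(rec.gyro_axis("yaw"), cfg)
    acc_hp = butter_filter(rec.acc_axis("yaw"), cfg.filter_order,
                           cfg.hp_poleoff_hz, "highpass")
    neg = find_peaks(acc_hp, cfg.min_prominence_acc, "negative").indices
    events: list[Event] = []
    missed = 0
    n_cyc = 0
    for a0, a1 in seg.cycles():
        n_cyc += 1
        i0, i1 = angle.index_at(a0), angle.index_at(a1)
        if i1 <= i0:
            missed += 1
            continue
        t_min = angle.time_at(i0 + int(np.argmin(angle.values[i0:i1 + 1])))
        cand = _peaks_in(neg, acc_hp, t_min - cfg.near_window_s,
                         t_min + cfg.near_window_s)
        if cand.size == 0:
            missed += 1
            continue
        best = cand[int(np.argmin(acc_hp.values[cand]))]
        events.append(Event(acc_hp.time_at(int(best)), "P_OFF", rec.side, "imu"))
    return DetectionResult(EventSeries(events), n_cycles=n_cyc, n_missed=missed)


def detect_ski_on(rec: IMURecording, seg: CycleSegmentation,
                  cfg: DetectionConfig = DetectionConfig()) -> DetectionResult:
    """S_ON per leg cycle: coarse at the drift-free roll-angle maximum,
    refined to the maximal raw vertical-acceleration peak nearby."""
    angle = _drift_free_angle(rec.gyro_axis("roll"), cfg)
    acc = rec.acc_axis("yaw")  # vertical component of the ski sensor
    pos = find_peaks(acc, cfg.min_prominence_acc, "positive").indices
    events: list[Event] = []
    missed = 0
    n_cyc = 0
    for a0, a1 in seg.cycles():
        n_cyc += 1
        i0, i1 = angle.index_at(a0), angle.index_at(a1)
        if i1 <= i0:
            missed += 1
            continue
        t_coarse = angle.time_at(i0 + int(np.argmax(angle.values[i0:i1 + 1])))
        cand = _peaks_in(pos, acc, t_coarse - cfg.near_window_s,
                         t_coarse + cfg.near_window_s)
        if cand.size == 0:
            missed += 1
            continue
        best = cand[int(np.argmax(acc.values[cand]))]
        events.append(Event(acc.time_at(int(best)), "S_ON", rec.side, "imu"))
    return DetectionResult(EventSeries(events), n_cycles=n_cyc, n_missed=missed)


def detect_ski_off(rec: IMURecording, seg: CycleSegmentation,
                   cfg: DetectionConfig = DetectionConfig()) -> DetectionResult:
    """S_OFF per leg cycle: the roll-angle minimum in the cycle's final
    portion, refined to the most-negative raw vertical-acceleration peak."""
    angle = _drift_free_angle(rec.gyro_axis("roll"), cfg)
    acc = rec.acc_axis("yaw")
    neg = find_peaks(acc, cfg.min_prominence_acc, "negative").indices
    events: list[Event] = []
    missed = 0
    n_cyc = 0
    for a0, a1 in seg.cycles():
        n_cyc += 1
        t_tail = a1 - cfg.ski_off_tail_frac * (a1 - a0)
        i0, i1 = angle.index_at(t_tail), angle.index_at(a1)
        if i1 <= i0:
            missed += 1
            continue
        t_min = angle.time_at(i0 + int(np.argmin(angle.values[i0:i1 + 1])))
        cand = _peaks_in(neg, acc, t_min - cfg.near_window_s,
                         t_min + cfg.near_window_s)
        if cand.size == 0:
            missed += 1
            continue
        best = cand[int(np.argmin(acc.values[cand]))]
        events.append(Event(acc.time_at(int(best)), "S_OFF", rec.side, "imu"))
    return DetectionResult(EventSeries(events), n_cycles=n_cyc, n_missed=missed)


def enforce_alternation(series: EventSeries) -> tuple[EventSeries, int]:
    """Drop events that break ON/OFF alternation within each (family, side).

    A missed constituent peak leaves its partner event unbalanced; the
    repair keeps complete ON/OFF pairs: of two consecutive OFFs the later is
    dropped, of two consecutive ONs the earlier.  Returns the repaired
    series and the number of dropped events (counted as misses).
    """
    dropped = 0
    keys = {(e.family, e.side) for e in series.events}
    kept: list[Event] = []
    for fam, side in sorted(keys):
        sub = [e for e in series.events if e.family == fam and e.side == side]
        out: list[Event] = []
        for e in sub:
            if out and out[-1].is_on() == e.is_on():
                if e.is_on():
                    out[-1] = e      # ON,ON: keep the newer
                # OFF,OFF: keep the earlier (drop e)
                dropped += 1
            else:
                out.append(e)
        kept.extend(out)
    return EventSeries(kept, trial_id=series.trial_id,
                       refractory_s=series.refractory_s), dropped


def detect_wrist_events(rec: IMURecording,
                        cfg: DetectionConfig = DetectionConfig()
                        ) -> tuple[EventSeries, dict]:
    """Full wrist pipeline: segmentation, P_ON, P_OFF, alternation repair.

    Returns the event series and a miss-accounting dict with keys
    ``n_cycles``, ``P_ON_missed``, ``P_OFF_missed``, ``dropped``.
    """
    seg = segment_wrist_cycles(rec, cfg)
    on = detect_pole_on(rec, seg, cfg)
    off = detect_pole_off(rec, seg, cfg)
    series = on.events.merged_with(off.events.events)
    series, dropped = enforce_alternation(series)
    counts = {"n_cycles": on.n_cycles, "P_ON_missed": on.n_missed,
              "P_OFF_missed": off.n_missed, "dropped": dropped}
    return series.validate(), counts


def detect_ski_events(rec: IMURecording,
                      cfg: DetectionConfig = DetectionConfig()
                      ) -> tuple[EventSeries, dict]:
    """Full ski pipeline: segmentation, S_ON, S_OFF, alternation repair."""
    seg = segment_ski_cycles(rec, cfg)
    on = detect_ski_on(rec, seg, cfg)
    off = detect_ski_off(rec, seg, cfg)
    series = on.events.merged_with(off.events.events)
    series, dropped = enforce_alternation(series)
    counts = {"n_cycles": on.n_cycles, "S_ON_missed": on.n_missed,
              "S_OFF_missed": off.n_missed, "dropped": dropped}
    return series.validate(), counts
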