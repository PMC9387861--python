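"""Assembly of per-limb events into skiing cycles and inner-cycle phases.

A skiing cycle starts when the left ski hits the ground and ends at the
next left-ski contact (half-open interval, so every event belongs to exactly
one cycle).  Left and right pole events are merged — near-synchronous
plants collapse to one action at their mean time — before pole phases are
computed, so the merged-plant count per cycle (2 in G3, 1 in G2/G4) feeds
the sub-technique decision tree directly.

Phases: S_CT = S_OFF − S_ON and S_SW = next S_ON − S_OFF per side,
P_CT = P_OFF − P_ON and P_SW = next P_ON − P_OFF on the merged pole stream,
S_CY the left-ski contact-to-contact duration, plus the pole–ski synchrony
delays.  A phase whose constituent events are missing is undefined (NaN),
never imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from skate_events.errors import NoCyclesError
from skate_events.reference_detection import Event, EventSeries

__all__ = ["CycleRecord", "define_cycles", "merge_pole_sides", "compute_phases",
           "PHASE_NAMES"]

log = logging.getLogger(__name__)

PHASE_NAMES = ("S_CY", "S_CT_left", "S_SW_left", "S_CT_right", "S_SW_right",
               "P_CT", "P_SW")


@dataclass
class CycleRecord:
    """One skiing cycle with its inner-cycle temporal parameters (seconds).

    Undefined phases are NaN.  ``delay_Pon_Son`` is the absolute value of
    the shortest time difference between a merged P_ON and any S_ON of the
    cycle; ``delay_Soff_Poff`` is P_OFF minus the nearest preceding S_OFF
    (positive when the pole leaves the ground after the ski).
    """

    cycle_id: int
    t_start: float
    t_end: float
    S_CT_left: float = math.nan
    S_SW_left: float = math.nan
    S_CT_right: float = math.nan
    S_SW_right: float = math.nan
    P_CT: float = math.nan
    P_SW: float = math.nan
    delay_Pon_Son: float = math.nan
    delay_Soff_Poff: float = math.nan
    n_pole_plants: int = 0
    subtech: str = "NaN"

    @property
    def S_CY(self) -> float:
        return self.t_end - self.t_start

    def phase(self, name: str) -> float:
        if name == "S_CY":
            return self.S_CY
        return getattr(self, name)

    def shifted(self, dt: float) -> "CycleRecord":
        r = CycleRecord(**{**self.__dict__})
        r.t_start += dt
        r.t_end += dt
        return r


def define_cycles(left_ski_events: EventSeries) -> list[tuple[float, float]]:
    """Cycle intervals [k-th left S_ON, (k+1)-th left S_ON).

    The last S_ON opens no cycle.  Raises :class:`NoCyclesError` with fewer
    than two left-ski contacts.
    """
    t = left_ski_events.times("S_ON", "left")
    if t.size < 2:
        raise NoCyclesError(f"need >= 2 left S_ON events, got {t.size}")
    return list(zip(t[:-1].tolist(), t[1:].tolist()))


def _pair_times(a: np.ndarray, b: np.ndarray, window_s: float
                ) -> list[tuple[int, int]]:
    """Optimal one-to-one pairing of two time lists: maximize the number of
    pairs within ``window_s``, then minimize total |difference|."""
    if a.size == 0 or b.size == 0:
        return []
    cost = np.abs(a[:, None] - b[None, :])
    feasible = cost <= window_s
    big = window_s * (a.size + b.size + 1) + np.sum(cost) + 1.0
    cost = np.where(feasible, cost, big)
    ri, ci = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(ri, ci) if feasible[i, j]]


def merge_pole_sides(left: EventSeries, right: EventSeries,
                     sync_window_s: float = 0.12) -> EventSeries:
    """Merge near-synchronous left/right pole events into single actions.

    P_ON (and P_OFF) pairs within ``sync_window_s`` merge into one event of
    side 'merged' at their mean time; unpaired events pass through (also
    re-labelled 'merged' so downstream code sees one stream).  Pairing is
    the optimal one-to-one assignment minimizing total within-window
    distance.
    """
    out: list[Event] = []
    for etype in ("P_ON", "P_OFF"):
        tl = left.times(etype)
        tr = right.times(etype)
        pairs = _pair_times(tl, tr, sync_window_s)
        used_l = {i for i, _ in pairs}
        used_r = {j for _, j in pairs}
        src = "imu"
        evs = list(left.select(etype)) + list(right.select(etype))
        if evs:
            src = evs[0].source
        for i, j in pairs:
            out.append(Event(0.5 * (tl[i] + tr[j]), etype, "merged", src))
        out.extend(Event(tl[i], etype, "merged", src)
                   for i in range(tl.size) if i not in used_l)
        out.extend(Event(tr[j], etype, "merged", src)
                   for j in range(tr.size) if j not in used_r)
    merged = EventSeries(out, trial_id=left.trial_id or right.trial_id)
    try:
        merged.validate()
    except Exception:
        # unpaired same-type events on both sides can break strict
        # alternation; retained by contract, so only warn
        log.warning("merged pole stream is not strictly alternating")
    return merged


def _first_after(times: np.ndarray, t: float, t_max: float | None = None
                 ) -> float:
    after = times[times > t]
    if t_max is not None:
        after = after[after <= t_max]
    return float(after[0]) if after.size else math.nan


def compute_phases(cycles: list[tuple[float, float]],
                   ski_events: EventSeries,
                   merged_pole_events: EventSeries) -> list[CycleRecord]:
    """Inner-cycle temporal parameters for each cycle.

    ``ski_events`` holds S_ON/S_OFF for both sides; ``merged_pole_events``
    the merged pole stream.  For cycles with several pole actions (G3), P_CT
    and P_SW are the means over the actions that are fully defined.  A
    follow-up event further than one cycle duration away marks the phase
    undefined rather than bridging a detection gap.
    """
    s_on = {s: ski_events.times("S_ON", s) for s in ("left", "right")}
    s_off = {s: ski_events.times("S_OFF", s) for s in ("left", "right")}
    p_on = merged_pole_events.times("P_ON")
    p_off = merged_pole_events.times("P_OFF")
    all_s_on = np.sort(np.concatenate([s_on["left"], s_on["right"]]))

    records: list[CycleRecord] = []
    for k, (t0, t1) in enumerate(cycles):
        rec = CycleRecord(cycle_id=k, t_start=t0, t_end=t1)
        s_cy = t1 - t0
        # per-side ski phases: first S_ON of the side inside [t0, t1)
        for side in ("left", "right"):
            on = s_on[side][(s_on[side] >= t0) & (s_on[side] < t1)]
            if on.size == 0:
                continue
            on_t = float(on[0])
            off_t = _first_after(s_off[side], on_t, on_t + s_cy)
            if math.isnan(off_t):
                continue
            setattr(rec, f"S_CT_{side}", off_t - on_t)
            nxt = _first_after(s_on[side], off_t, on_t + 1.5 * s_cy)
            if not math.isnan(nxt):
                setattr(rec, f"S_SW_{side}", nxt - off_t)
        # merged pole phases
        on_in = p_on[(p_on >= t0) & (p_on < t1)]
        rec.n_pole_plants = int(on_in.size)
        cts, sws = [], []
        for on_t in on_in:
            off_t = _first_after(p_off, on_t, on_t + s_cy)
            if math.isnan(off_t):
                continue
            cts.append(off_t - on_t)
            nxt = _first_after(p_on, off_t, off_t + 1.5 * s_cy)
            if not math.isnan(nxt):
                sws.append(nxt - off_t)
        if cts:
            rec.P_CT = float(np.mean(cts))
        if sws:
            rec.P_SW = float(np.mean(sws))
        # pole-ski synchrony delays
        if on_in.size and all_s_on.size:
            rec.delay_Pon_Son = float(
                np.min(np.abs(on_in[:, None] - all_s_on[None, :])))
        off_in = p_off[(p_off >= t0) & (p_off < t1)]
        all_s_off = np.sort(np.concatenate([s_off["left"], s_off["right"]]))
        if off_in.size and all_s_off.size:
            po = float(off_in[0])
            prev = all_s_off[all_s_off <= po]
            if prev.size:
                rec.delay_Soff_Poff = po - float(prev[-1])
        records.append(rec)
    return records
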