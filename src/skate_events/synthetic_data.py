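"""Synthetic roller-ski skating trials with known ground truth.

The generator emulates the *temporal structure* of the G2/G3/G4 skating
sub-techniques — not full-body biomechanics.  Each trial is built in three
layers:

1. :func:`schedule_events` lays out ground-truth contact events on a cycle
   grid: left ski contact opens each cycle, the right ski follows half a
   cycle later, contact occupies ≈55 % of the cycle per ski, and pole
   plants follow the sub-technique's coordination pattern (two merged
   plants per cycle in G3; one synchronous plant in G4; one offset plant in
   G2).  Independent Gaussian jitter on every event models stride-to-stride
   variability; cycles whose jitter breaks ON/OFF alternation are
   rejection-resampled.
2. :func:`render_marker_tracks` converts the schedule into vertical marker
   trajectories: flat ground-contact plateaus joined by raised-cosine
   flight arcs, C¹-continuous, whose curvature maxima sit at the contact
   times by construction; sampled at the camera rate with millimetre noise.
3. :func:`render_imu_streams` converts the schedule into four 6-channel IMU
   recordings whose waveforms carry exactly the features the detectors look
   for: a wrist yaw angle peaking just before each pole plant, a
   negative-then-positive acceleration doublet at P_ON, a sharp
   high-frequency transient at P_OFF, a ski roll oscillation at the leg
   rate (plus gyro bias), and vertical acceleration spikes at S_ON/S_OFF —
   all with white sensor noise.

One root seed drives everything; per-stream child seeds are derived
deterministically via ``numpy.random.SeedSequence.spawn``, so a trial is
bit-identical for a given spec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from skate_events.errors import GeneratorInfeasibleError, InvalidParameterError
from skate_events.reference_detection import Event, EventSeries, family_of
from skate_events.signal_core import IMURecording, MarkerTrack, UniformSeries, butter_filter

__all__ = ["TrialSpec", "GroundTruth", "SimulatedTrial",
           "schedule_events", "render_marker_tracks", "render_imu_streams",
           "simulate_trial", "DEFAULT_CYCLE_RATES"]

#: Default cycle rates (Hz) per sub-technique, matching the protocol's
#: incline/speed grid: G2 on steep uphill cycles fastest, G4 on flat slowest.
DEFAULT_CYCLE_RATES = {"G2": 0.9, "G3": 0.8, "G4": 0.7}

#: Fraction of the cycle each ski spends on the ground.
SKI_CONTACT_FRAC = 0.55
#: Fraction of the cycle a pole spends on the ground.
POLE_CONTACT_FRAC = 0.30
#: Lag of the right wrist behind the left in a (near-)synchronous plant, s.
ARM_SYNC_LAG_S = 0.015
#: Pole-ski synchrony of a "synchronous" plant (G3/G4), s: the merged
#: left/right plant trails the ski contact by this much.  Kept near the
#: upper edge of the 30 ms synchrony band so that event jitter rarely
#: carries the cycle-opening plant across the cycle boundary.
SYNC_PLANT_LAG_S = 0.0275
#: G2 plant offset from the nearest ski contact, as a fraction of the cycle.
G2_OFFSET_FRAC = 0.20
#: Minimum time between consecutive events of one (family, side) stream, s.
MIN_EVENT_GAP_S = 0.05


@dataclass(frozen=True)
class TrialSpec:
    """Conditions of one synthetic trial.

    Defaults reproduce the study conditions the validation batch uses:
    256 Hz IMUs, 200 Hz markers, 0.5 m·s⁻² accelerometer noise, 2 deg·s⁻¹
    gyro noise, 0.5 deg·s⁻¹ gyro bias, 10 ms event jitter, no inter-system
    clock offset, and per-technique cycle rates from the protocol grid.
    """

    subtech: str = "G3"
    n_cycles: int = 50
    cycle_rate: float | None = None       # Hz; None -> technique default
    fs_imu: float = 256.0
    fs_ref: float = 200.0
    noise_acc_sd: float = 0.5             # m·s⁻²
    noise_gyro_sd: float = 2.0            # deg·s⁻¹
    noise_marker_sd: float = 0.001        # m
    gyro_bias: float = 0.5                # deg·s⁻¹
    jitter_sd_s: float = 0.010
    imu_offset_s: float = 0.0
    two_wheel_split_s: float = 0.0        # 0 disables the two-wheel S_ON
    seed: int = 0

    def __post_init__(self):
        if self.subtech not in ("G2", "G3", "G4", "mixed"):
            raise InvalidParameterError(f"unknown sub-technique {self.subtech!r}")
        if self.n_cycles < 2:
            raise InvalidParameterError("n_cycles must be >= 2")
        for name in ("noise_acc_sd", "noise_gyro_sd", "noise_marker_sd",
                     "jitter_sd_s", "fs_imu", "fs_ref"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")

    @property
    def rate(self) -> float:
        if self.cycle_rate is not None:
            return self.cycle_rate
        if self.subtech == "mixed":
            return DEFAULT_CYCLE_RATES["G3"]
        return DEFAULT_CYCLE_RATES[self.subtech]


@dataclass
class GroundTruth:
    """The generator's answer key for one trial.

    ``events`` covers the counted cycles (plus the left-ski contact closing
    the last cycle); ``events_extended`` additionally includes one warm-up
    and one cool-down cycle whose kinematics are rendered so that counted
    events near the trial edges remain detectable but are not scored.
    """

    events: EventSeries
    events_extended: EventSeries
    labels: list[str]
    cycle_starts: np.ndarray            # counted left S_ON times, n_cycles+1
    spec: TrialSpec
    duration_s: float = 0.0

    def phase_records(self):
        """Exact inner-cycle phases of the ground-truth schedule."""
        from skate_events.cycle_analysis import (
            compute_phases, define_cycles, merge_pole_sides)
        cycles = define_cycles(self.events.select("S_ON", side="left"))
        merged = merge_pole_sides(self.events.select(family="pole", side="left"),
                                  self.events.select(family="pole", side="right"))
        return compute_phases(cycles, self.events.select(family="ski"), merged)


@dataclass
class SimulatedTrial:
    gt: GroundTruth
    markers: dict            # location -> MarkerTrack
    imus: dict               # location -> IMURecording


def _cycle_template(subtech: str, T: float) -> dict:
    """Event times of one cycle relative to its start, before jitter."""
    ev = {
        ("S_ON", "left"): [0.0],
        ("S_OFF", "left"): [SKI_CONTACT_FRAC * T],
        ("S_ON", "right"): [0.5 * T],
        ("S_OFF", "right"): [(0.5 + SKI_CONTACT_FRAC) * T],
    }
    if subtech == "G3":
        plants = [SYNC_PLANT_LAG_S, 0.5 * T + SYNC_PLANT_LAG_S]
    elif subtech == "G4":
        # anchored to the mid-cycle (right-ski) push: synchronous, and far
        # from the cycle boundary that jitter could carry a plant across
        plants = [0.5 * T + SYNC_PLANT_LAG_S]
    elif subtech == "G2":
        plants = [G2_OFFSET_FRAC * T]
    else:
        raise InvalidParameterError(subtech)
    for side in ("left", "right"):
        # the two arms straddle the nominal plant time, so the merged
        # (mean-time) plant sits exactly at it
        lag = -0.5 * ARM_SYNC_LAG_S if side == "left" else 0.5 * ARM_SYNC_LAG_S
        ev[("P_ON", side)] = [p + lag for p in plants]
        ev[("P_OFF", side)] = [p + lag + POLE_CONTACT_FRAC * T for p in plants]
    return ev


def _stream_ok(times_types: list[tuple[float, bool]]) -> bool:
    """Alternation + minimum-gap check on one (family, side) stream."""
    prev_t, prev_on = None, None
    for t, is_on in times_types:
        if prev_t is not None:
            if is_on == prev_on or t - prev_t < MIN_EVENT_GAP_S:
                return False
        prev_t, prev_on = t, is_on
    return True


def schedule_events(spec: TrialSpec) -> GroundTruth:
    """Lay out the ground-truth event schedule for one trial."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    T = 1.0 / spec.rate
    n = spec.n_cycles
    pad = 0.5
    # cycle k in -1..n; k = -1 is warm-up, k = n cool-down
    cyc_ids = list(range(-1, n + 1))
    techniques = {}
    for k in cyc_ids:
        if spec.subtech == "mixed":
            techniques[k] = ("G2", "G3", "G4")[rng.integers(3)]
        else:
            techniques[k] = spec.subtech

    # raw (unjittered) schedule: list of [time, etype, side, cycle]
    raw: list[list] = []
    for k in cyc_ids:
        s_k = pad + (k + 1) * T
        for (etype, side), times in _cycle_template(techniques[k], T).items():
            for t in times:
                raw.append([s_k + t, etype, side, k])
    duration = pad + (n + 2) * T + 0.8 * T + pad

    # jitter with rejection-resampling of alternation/gap violations
    times = np.array([r[0] for r in raw])
    jit = rng.normal(0.0, spec.jitter_sd_s, size=times.size) \
        if spec.jitter_sd_s > 0 else np.zeros(times.size)
    streams: dict[tuple, list[int]] = {}
    for i, r in enumerate(raw):
        streams.setdefault((family_of(r[1]), r[2]), []).append(i)
    first_pass_bad: set[int] = set()
    for attempt in range(200):
        bad: set[int] = set()
        jt = times + jit
        for idxs in streams.values():
            order = sorted(idxs, key=lambda i: times[i])
            for a, b in zip(order, order[1:]):
                pair = [(jt[a], raw[a][1].endswith("_ON")),
                        (jt[b], raw[b][1].endswith("_ON"))]
                if not _stream_ok(pair):
                    bad.update((a, b))
        if attempt == 0:
            first_pass_bad = set(bad)
            bad_cycles = {raw[i][3] for i in first_pass_bad}
            if len(bad_cycles) > 0.10 * (n + 2):
                raise GeneratorInfeasibleError(
                    f"jitter sd {spec.jitter_sd_s}s breaks alternation in "
                    f"{len(bad_cycles)}/{n + 2} cycles")
        if not bad:
            break
        for i in bad:
            jit[i] = rng.normal(0.0, spec.jitter_sd_s)
    else:
        raise GeneratorInfeasibleError("alternation repair did not converge")
    jt = times + jit

    def mk_events(pred):
        return [Event(float(jt[i]), r[1], r[2], "ground_truth")
                for i, r in enumerate(raw) if pred(r)]

    counted = mk_events(lambda r: 0 <= r[3] < n or
                        (r[3] == n and r[1] == "S_ON" and r[2] == "left"))
    extended = mk_events(lambda r: True)
    labels = [techniques[k] for k in range(n)]
    starts = np.sort([float(jt[i]) for i, r in enumerate(raw)
                      if r[1] == "S_ON" and r[2] == "left" and 0 <= r[3] <= n])
    gt = GroundTruth(
        events=EventSeries(counted, trial_id=f"synthetic-{spec.subtech}-{spec.seed}").validate(),
        events_extended=EventSeries(extended).validate(),
        labels=labels,
        cycle_starts=starts,
        spec=spec,
        duration_s=duration,
    )
    return gt


def _gauss(t: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / sd) ** 2)


def _contact_pairs(series: EventSeries, family: str, side: str
                   ) -> list[tuple[float, float]]:
    sub = series.select(family=family, side=side)
    pairs = []
    pending_on = None
    for e in sub:
        if e.is_on():
            pending_on = e.time
        elif pending_on is not None:
            pairs.append((pending_on, e.time))
            pending_on = None
    return pairs


def render_marker_tracks(gt: GroundTruth, spec: TrialSpec | None = None
                         ) -> dict[str, MarkerTrack]:
    """Vertical marker trajectories for the two pole tips and two skis.

    Ground contact is a z≈0 plateau; flights are raised-cosine arcs with a
    per-flight random apex height in [0.05, 0.25] m, C¹-continuous at the
    junctions, where the curvature (second derivative of z) attains its
    maxima — exactly the feature the reference detector looks for.
    """
    spec = spec or gt.spec
    ss = np.random.SeedSequence(spec.seed).spawn(9)
    tracks: dict[str, MarkerTrack] = {}
    t = np.arange(0.0, gt.duration_s, 1.0 / spec.fs_ref)
    locations = (("pole_tip_left", "pole", "left", 1),
                 ("pole_tip_right", "pole", "right", 2),
                 ("ski_left", "ski", "left", 3),
                 ("ski_right", "ski", "right", 4))
    for loc, fam, side, child in locations:
        rng = np.random.default_rng(ss[child])
        contacts = _contact_pairs(gt.events_extended, fam, side)
        z = np.zeros_like(t)
        # flight arcs between consecutive contacts, plus half-arcs at the ends
        swings = [b[0] - a[1] for a, b in zip(contacts, contacts[1:])]
        mean_swing = float(np.mean(swings)) if swings else 0.5
        flight_windows = []
        if contacts:
            flight_windows.append((contacts[0][0] - mean_swing, contacts[0][0]))
        for a, b in zip(contacts, contacts[1:]):
            flight_windows.append((a[1], b[0]))
        if contacts:
            last_off = contacts[-1][1]
            flight_windows.append((last_off, last_off + mean_swing))
        for t_off, t_on in flight_windows:
            dur = t_on - t_off
            if dur <= 0:
                continue
            h = rng.uniform(0.05, 0.25)
            sel = (t > t_off) & (t < t_on)
            u = (t[sel] - t_off) / dur
            z[sel] = 0.5 * h * (1.0 - np.cos(2.0 * np.pi * u))
        if spec.noise_marker_sd > 0:
            z = z + rng.normal(0.0, spec.noise_marker_sd, size=z.size)
        tracks[loc] = MarkerTrack(
            loc, UniformSeries(0.0, spec.fs_ref, z, label=f"{loc}_z", units="m"))
    return tracks


def _angle_profile(t: np.ndarray, knots_t: list[float], knots_v: list[float],
                   duration: float):
    """Pchip angle through control points; returns (angle, rate, angular acc)."""
    kt = [min(knots_t[0], 0.0) - 0.5] + list(knots_t) + [max(duration, knots_t[-1]) + 0.5]
    kv = [0.0] + list(knots_v) + [0.0]
    f = PchipInterpolator(kt, kv)
    return f(t), f.derivative(1)(t), f.derivative(2)(t)


def render_imu_streams(gt: GroundTruth, spec: TrialSpec | None = None
                       ) -> dict[str, IMURecording]:
    """Four IMU recordings (two wrists, two skis) for one trial.

    Wrist: yaw angle peaks shortly before each P_ON and bottoms at P_OFF
    (pchip through those control points); yaw acceleration is a scaled,
    band-limited angular acceleration plus a sharp negative-then-positive
    doublet at P_ON and a ~10 ms negative transient at P_OFF.  Ski: roll
    angle peaks at S_ON and bottoms at S_OFF; vertical (yaw-axis)
    acceleration carries a dominant positive spike at S_ON (optionally
    split to emulate the two wheels landing separately) and a negative
    spike at S_OFF.  Unused channels carry band-limited motion-free noise.
    All channels get white Gaussian noise; streams are shifted by the
    inter-system clock offset.
    """
    spec = spec or gt.spec
    ss = np.random.SeedSequence(spec.seed).spawn(9)
    fs = spec.fs_imu
    t = np.arange(0.0, gt.duration_s, 1.0 / fs)
    # physical (marker-clock) time of IMU sample k is t[k] - imu_offset_s
    tp = t - spec.imu_offset_s
    recs: dict[str, IMURecording] = {}

    def series(vals, label, units):
        return UniformSeries(0.0, fs, vals, label=label, units=units)

    def noisy(vals, sd, rng):
        return vals + rng.normal(0.0, sd, size=vals.size) if sd > 0 else vals

    for loc, child in (("wrist_left", 5), ("wrist_right", 6)):
        rng = np.random.default_rng(ss[child])
        side = loc.rsplit("_", 1)[1]
        plants = _contact_pairs(gt.events_extended, "pole", side)
        kt, kv = [], []
        for on, off in plants:
            # the yaw-angle maximum sits on the steep flank of the plant
            # deceleration, just before P_ON, as in real poling kinematics
            kt += [on - 0.012, off]
            kv += [25.0, -25.0]
        angle, rate, aacc = _angle_profile(tp, kt, kv, gt.duration_s)
        # band-limit the piecewise-polynomial angular acceleration so knot
        # discontinuities do not leak into the 5 Hz high-pass band
        base = butter_filter(series(aacc, "", ""), 2, 6.0, "lowpass").values
        acc = base / 1000.0 * 1.2
        for on, off in plants:
            a1, a2, a3 = rng.uniform(5, 8), rng.uniform(5, 8), rng.uniform(4, 8)
            acc = acc - a1 * _gauss(tp, on, 0.008) \
                      + a2 * _gauss(tp, on + 0.025, 0.008) \
                      - a3 * _gauss(tp, off, 0.004)
        gyro_yaw = noisy(rate + spec.gyro_bias, spec.noise_gyro_sd, rng)
        acc_yaw = noisy(acc, spec.noise_acc_sd, rng)
        other = [noisy(0.3 * rate / 50.0, spec.noise_acc_sd, rng) for _ in range(2)]
        gother = [noisy(0.2 * rate, spec.noise_gyro_sd, rng) for _ in range(2)]
        # axis_map yaw->z, roll->x, pitch->y
        recs[loc] = IMURecording(
            location=loc,
            acc=(series(other[0], "acc_x", "m·s⁻²"),
                 series(other[1], "acc_y", "m·s⁻²"),
                 series(acc_yaw, "acc_z", "m·s⁻²")),
            gyro=(series(gother[0], "gyr_x", "deg·s⁻¹"),
                  series(gother[1], "gyr_y", "deg·s⁻¹"),
                  series(gyro_yaw, "gyr_z", "deg·s⁻¹")),
        )

    for loc, child in (("ski_left", 7), ("ski_right", 8)):
        rng = np.random.default_rng(ss[child])
        side = loc.rsplit("_", 1)[1]
        contacts = _contact_pairs(gt.events_extended, "ski", side)
        kt, kv = [], []
        for on, off in contacts:
            kt += [on, off]
            kv += [15.0, -15.0]
        angle, rate, _ = _angle_profile(tp, kt, kv, gt.duration_s)
        acc = np.zeros_like(tp)
        for on, off in contacts:
            a_on, a_off = rng.uniform(6, 10), rng.uniform(6, 10)
            acc = acc + a_on * _gauss(tp, on, 0.008) - a_off * _gauss(tp, off, 0.008)
            if spec.two_wheel_split_s > 0:
                acc = acc + 0.6 * a_on * _gauss(tp, on - spec.two_wheel_split_s, 0.008)
        gyro_roll = noisy(rate + spec.gyro_bias, spec.noise_gyro_sd, rng)
        acc_vert = noisy(acc, spec.noise_acc_sd, rng)
        other = [noisy(0.3 * rate / 50.0, spec.noise_acc_sd, rng) for _ in range(2)]
        gother = [noisy(0.2 * rate, spec.noise_gyro_sd, rng) for _ in range(2)]
        recs[loc] = IMURecording(
            location=loc,
            acc=(series(other[0], "acc_x", "m·s⁻²"),
                 series(other[1], "acc_y", "m·s⁻²"),
                 series(acc_vert, "acc_z", "m·s⁻²")),
            gyro=(series(gyro_roll, "gyr_x", "deg·s⁻¹"),
                  series(gother[0], "gyr_y", "deg·s⁻¹"),
                  series(gother[1], "gyr_z", "deg·s⁻¹")),
        )
    return recs


def simulate_trial(spec: TrialSpec) -> SimulatedTrial:
    """Schedule + render one full synthetic trial."""
    gt = schedule_events(spec)
    return SimulatedTrial(gt=gt,
                          markers=render_marker_tracks(gt, spec),
                          imus=render_imu_streams(gt, spec))
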