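"""Tests for the wrist and ski IMU event detectors."""

import dataclasses

import numpy as np
import pytest

from skate_events.errors import InsufficientCyclesError, InvalidParameterError
from skate_events.imu_detection import (
    DetectionConfig, detect_pole_on, detect_ski_events, detect_wrist_events,
    enforce_alternation, segment_ski_cycles, segment_wrist_cycles)
from skate_events.reference_detection import Event, EventSeries
from skate_events.signal_core import IMURecording, UniformSeries
from skate_events.synthetic_data import TrialSpec, simulate_trial
from skate_events.validation_stats import match_events

FS = 256.0


def make_imu(location, gyro_main, acc_main=None, fs=FS):
    """IMU recording with the semantic main axis populated.

    For wrists the main axis is yaw (channel z), for skis the gyro main
    axis is roll (channel x) and the acc main axis vertical/yaw (channel z).
    """
    n = len(gyro_main)
    zeros = np.zeros(n)
    acc_main = zeros if acc_main is None else np.asarray(acc_main, float)

    def ser(v, units):
        return UniformSeries(0.0, fs, v, units=units)

    if location.startswith("wrist"):
        gyro = (ser(zeros, "deg·s⁻¹"), ser(zeros, "deg·s⁻¹"),
                ser(gyro_main, "deg·s⁻¹"))
    else:
        gyro = (ser(gyro_main, "deg·s⁻¹"), ser(zeros, "deg·s⁻¹"),
                ser(zeros, "deg·s⁻¹"))
    acc = (ser(zeros, "m·s⁻²"), ser(zeros, "m·s⁻²"), ser(acc_main, "m·s⁻²"))
    return IMURecording(location=location, acc=acc, gyro=gyro)


class TestSegmentation:
    def test_wrist_sine_anchor_count_and_spacing(self):
        # yaw rate 360 sin(2pi 0.8 t): angle maxima every 1.25 s
        t = np.arange(0, 10, 1 / FS)
        rec = make_imu("wrist_left", 360.0 * np.sin(2 * np.pi * 0.8 * t))
        seg = segment_wrist_cycles(rec)
        assert abs(len(seg) - 8) <= 1
        assert np.allclose(np.diff(seg.anchors), 1.25, atol=0.02)

    def test_wrist_zero_gyro_insufficient_cycles(self):
        rec = make_imu("wrist_left", np.zeros(int(10 * FS)))
        with pytest.raises(InsufficientCyclesError) as ei:
            segment_wrist_cycles(rec)
        assert ei.value.count == 0

    def test_wrist_anchor_bias_invariance(self):
        # a 0.5 deg/s constant gyro bias integrates to a ramp that the
        # 0.1 Hz high-pass removes
        t = np.arange(0, 10, 1 / FS)
        rate = 360.0 * np.sin(2 * np.pi * 0.8 * t)
        a = segment_wrist_cycles(make_imu("wrist_left", rate)).anchors
        b = segment_wrist_cycles(make_imu("wrist_left", rate + 0.5)).anchors
        assert len(a) == len(b)
        assert np.max(np.abs(a - b)) <= 1 / FS + 1e-9

    def test_ski_sine_anchor_count(self):
        t = np.arange(0, 10, 1 / FS)
        rec = make_imu("ski_left", 90.0 * np.sin(2 * np.pi * 0.7 * t))
        seg = segment_ski_cycles(rec)
        assert abs(len(seg) - 7) <= 1

    def test_ski_zero_gyro_insufficient_cycles(self):
        with pytest.raises(InsufficientCyclesError):
            segment_ski_cycles(make_imu("ski_left", np.zeros(int(10 * FS))))

    def test_ski_anchor_count_robust_to_noise(self, rng):
        t = np.arange(0, 10, 1 / FS)
        rate = 90.0 * np.sin(2 * np.pi * 0.7 * t)
        clean = segment_ski_cycles(make_imu("ski_left", rate))
        noisy = segment_ski_cycles(
            make_imu("ski_left", rate + rng.normal(0, 10, size=t.size)))
        assert len(noisy) == len(clean)

    def test_wrong_location_rejected(self):
        rec = make_imu("ski_left", np.sin(np.arange(0, 10, 1 / FS)) * 90)
        with pytest.raises(InvalidParameterError):
            segment_wrist_cycles(rec)


def _recovery(gt_series, det_series, etype, side, tol_samples, fs=FS):
    m = match_events(gt_series.select(etype, side),
                     det_series.select(etype, side), 0.6)
    return m, (np.max(np.abs(m.errors_s)) if m.pairs else 0.0) <= tol_samples / fs + 1e-9


class TestGeneratorRecovery:
    def test_noiseless_events_within_two_samples(self, clean_trial):
        gt = clean_trial.gt
        wrist, _ = detect_wrist_events(clean_trial.imus["wrist_left"])
        ski, _ = detect_ski_events(clean_trial.imus["ski_left"])
        for et, det in (("P_ON", wrist), ("P_OFF", wrist),
                        ("S_ON", ski), ("S_OFF", ski)):
            m, ok = _recovery(gt.events, det, et, "left", 2)
            assert len(m.missed_ref) == 0, et
            assert ok, et

    def test_amplitude_scale_invariance(self, clean_trial):
        # doubling all acceleration amplitudes must leave peak (and hence
        # event) locations unchanged
        rec = clean_trial.imus["wrist_left"]
        doubled = IMURecording(
            location=rec.location,
            acc=tuple(s.with_values(2.0 * s.values) for s in rec.acc),
            gyro=rec.gyro, axis_map=rec.axis_map)
        base, _ = detect_wrist_events(rec)
        scaled, _ = detect_wrist_events(doubled)
        assert np.allclose(base.times(), scaled.times())

    def test_time_shift_equivariance(self, clean_trial):
        rec = clean_trial.imus["ski_left"]
        dt = 3.0
        shifted = IMURecording(
            location=rec.location,
            acc=tuple(s.shifted(dt) for s in rec.acc),
            gyro=tuple(s.shifted(dt) for s in rec.gyro),
            axis_map=rec.axis_map)
        base, _ = detect_ski_events(rec)
        moved, _ = detect_ski_events(shifted)
        assert len(base) == len(moved)
        assert np.max(np.abs(moved.times() - base.times() - dt)) <= 1 / FS + 1e-9

    def test_two_wheel_landing_snaps_to_larger_spike(self):
        # the smaller first-wheel spike precedes the main spike; detection
        # must snap to the larger one, which carries the ground-truth time
        spec = TrialSpec(subtech="G4", n_cycles=10, seed=3, noise_acc_sd=0.0,
                         noise_gyro_sd=0.0, jitter_sd_s=0.0, gyro_bias=0.0,
                         two_wheel_split_s=0.04)
        trial = simulate_trial(spec)
        ski, counts = detect_ski_events(trial.imus["ski_left"])
        m, ok = _recovery(trial.gt.events, ski, "S_ON", "left", 2)
        assert len(m.missed_ref) == 0
        assert ok

    def test_flat_acceleration_all_missed(self):
        # plausible roll oscillation but no vertical spikes: every cycle is
        # a miss, and miss accounting covers all cycles
        t = np.arange(0, 12, 1 / FS)
        rec = make_imu("ski_left", 60.0 * np.sin(2 * np.pi * 0.8 * t))
        events, counts = detect_ski_events(rec)
        assert len(events) == 0
        assert counts["S_ON_missed"] == counts["n_cycles"]
        assert counts["S_OFF_missed"] == counts["n_cycles"]

    def test_smooth_wrist_trace_misses_pole_off(self, clean_trial):
        # a trace with no content above 5 Hz cannot contain a P_OFF
        # transient: the high-passed signal carries no prominent peaks
        t = np.arange(0, 12, 1 / FS)
        rate = 400.0 * np.sin(2 * np.pi * 0.8 * t)
        acc = 3.0 * np.sin(2 * np.pi * 0.8 * t + 1.0)
        rec = make_imu("wrist_left", rate, acc_main=acc)
        events, counts = detect_wrist_events(rec)
        assert counts["P_OFF_missed"] == counts["n_cycles"]

    def test_miss_accounting_conserves_cycles(self, noisy_trial):
        for loc in ("wrist_left", "wrist_right"):
            ev, c = detect_wrist_events(noisy_trial.imus[loc])
            n_on = len(ev.select("P_ON"))
            assert n_on + c["P_ON_missed"] == c["n_cycles"]


class TestEnforceAlternation:
    def test_orphan_off_dropped(self):
        evs = [Event(1.0, "P_ON", "left", "imu"), Event(1.4, "P_OFF", "left", "imu"),
               Event(2.4, "P_OFF", "left", "imu"), Event(3.0, "P_ON", "left", "imu")]
        out, dropped = enforce_alternation(EventSeries(evs))
        assert dropped == 1
        assert [e.time for e in out] == [1.0, 1.4, 3.0]

    def test_consecutive_ons_keep_newer(self):
        evs = [Event(1.0, "P_ON", "left", "imu"), Event(2.0, "P_ON", "left", "imu"),
               Event(2.4, "P_OFF", "left", "imu")]
        out, dropped = enforce_alternation(EventSeries(evs))
        assert dropped == 1
        assert [e.time for e in out] == [2.0, 2.4]

    def test_valid_series_untouched(self):
        evs = [Event(1.0, "S_ON", "left", "imu"), Event(1.6, "S_OFF", "left", "imu")]
        out, dropped = enforce_alternation(EventSeries(evs))
        assert dropped == 0 and len(out) == 2
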