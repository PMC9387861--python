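"""End-to-end orchestration: run both detectors on a trial, assemble
cycles and phases for each, pair them, and aggregate batch-level
validation metrics (detection rate, phase bias/precision, classification
accuracy).

These helpers sit on top of the module-level operations; the CLI and the
validation scripts are thin wrappers around them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from skate_events.classification import TreeConfig, classify_trial
from skate_events.cycle_analysis import (
    CycleRecord, compute_phases, define_cycles, merge_pole_sides)
from skate_events.errors import NoCyclesError
from skate_events.imu_detection import (
    DetectionConfig, detect_ski_events, detect_wrist_events)
from skate_events.reference_detection import (
    EventSeries, detect_reference_events, ground_proximity)
from skate_events.synthetic_data import SimulatedTrial, TrialSpec, simulate_trial
from skate_events.validation_stats import (
    detection_rate, inter_trial_stats, intra_trial_stats, match_events)

__all__ = [
    "detect_trial_imu", "detect_trial_reference", "cycles_and_phases",
    "TrialEvaluation", "evaluate_trial", "BatchResult", "evaluate_batch",
    "make_batch_specs", "PHASES_POOLED",
]

#: Pooled phase names used in validation tables (sides pooled for the skis).
PHASES_POOLED = ("P_CT", "P_SW", "S_CT", "S_SW", "S_CY")

EVENT_STREAMS = [(et, side) for et in ("P_ON", "P_OFF", "S_ON", "S_OFF")
                 for side in ("left", "right")]


def detect_trial_imu(imus: dict, cfg: DetectionConfig = DetectionConfig(),
                     imu_offset_s: float = 0.0) -> tuple[EventSeries, dict]:
    """Run the wrist and ski detectors on all four IMUs of a trial.

    ``imu_offset_s`` is the known inter-system clock offset; detected times
    are mapped back onto the reference clock by subtracting it.
    """
    all_events: list = []
    counts: dict = {}
    for loc, rec in imus.items():
        if rec.is_wrist():
            ev, c = detect_wrist_events(rec, cfg)
        else:
            ev, c = detect_ski_events(rec, cfg)
        counts[loc] = c
        all_events.extend(ev.events)
    series = EventSeries(all_events)
    if imu_offset_s:
        series = series.shifted(-imu_offset_s)
    return series, counts


def detect_trial_reference(markers: dict, quantile: float = 0.1,
                           margin_m: float = 0.003,
                           window_s: float = 0.05,
                           smooth_hz: float | None = 20.0) -> EventSeries:
    """Run the marker-based reference detector on all four tracks."""
    all_events: list = []
    for track in markers.values():
        mask = ground_proximity(track, quantile=quantile, margin_m=margin_m)
        ev = detect_reference_events(track, mask, window_s=window_s,
                                     smooth_hz=smooth_hz)
        all_events.extend(ev.events)
    return EventSeries(all_events)


def cycles_and_phases(events: EventSeries,
                      tree_cfg: TreeConfig = TreeConfig(),
                      classify: bool = True) -> list[CycleRecord]:
    """Left-ski cycles, merged-pole phases and (optionally) sub-technique
    labels from one event stream."""
    cycles = define_cycles(events.select("S_ON", side="left"))
    merged = merge_pole_sides(events.select(family="pole", side="left"),
                              events.select(family="pole", side="right"))
    records = compute_phases(cycles, events.select(family="ski"), merged)
    if classify and records:
        classify_trial(records, cfg=tree_cfg)
    return records


def _median_cycle_s(events: EventSeries) -> float:
    t = events.times("S_ON", "left")
    if t.size < 2:
        return 1.25
    return float(np.median(np.diff(t)))


def _pair_records(ref: list[CycleRecord], other: list[CycleRecord],
                  max_gap_s: float) -> list[tuple[CycleRecord, CycleRecord]]:
    """Pair cycles across methods by nearest start time."""
    from skate_events.cycle_analysis import _pair_times
    a = np.array([r.t_start for r in ref])
    b = np.array([r.t_start for r in other])
    return [(ref[i], other[j]) for i, j in _pair_times(a, b, max_gap_s)]


@dataclass
class TrialEvaluation:
    """Everything measured on one synthetic trial."""

    spec: TrialSpec
    gt_event_counts: dict = field(default_factory=dict)       # (etype, side) -> n
    imu_matched_counts: dict = field(default_factory=dict)    # vs ground truth
    event_errors_ref_vs_imu: dict = field(default_factory=dict)   # (etype, side) -> list[s]
    phase_errors: dict = field(default_factory=dict)          # phase -> list[s], ref - imu
    phase_rel_errors: dict = field(default_factory=dict)      # phase -> list[%]
    n_cycles_gt: int = 0
    n_cycles_correct: int = 0

    @property
    def detection_pct(self) -> float:
        ref = sum(self.gt_event_counts.values())
        matched = sum(self.imu_matched_counts.values())
        return detection_rate(ref, matched)


def _phase_error_lists(ref_recs, imu_recs, max_gap_s):
    errors = {p: [] for p in PHASES_POOLED}
    rel = {p: [] for p in PHASES_POOLED}
    for rr, ir in _pair_records(ref_recs, imu_recs, max_gap_s):
        for phase in PHASES_POOLED:
            if phase in ("S_CT", "S_SW"):
                names = [f"{phase}_left", f"{phase}_right"]
            else:
                names = [phase]
            for nm in names:
                rv, iv = rr.phase(nm), ir.phase(nm)
                if math.isnan(rv) or math.isnan(iv):
                    continue
                err = rv - iv
                errors[phase].append(err)
                if rv > 0:
                    rel[phase].append(100.0 * err / rv)
    return errors, rel


def evaluate_trial(trial: SimulatedTrial,
                   det_cfg: DetectionConfig = DetectionConfig(),
                   tree_cfg: TreeConfig = TreeConfig()) -> TrialEvaluation:
    """Full two-system evaluation of one simulated trial against its
    ground truth."""
    gt = trial.gt
    spec = gt.spec
    imu_events, _ = detect_trial_imu(trial.imus, det_cfg,
                                     imu_offset_s=spec.imu_offset_s)
    ref_events = detect_trial_reference(trial.markers)
    max_gap = 0.5 * _median_cycle_s(gt.events)

    ev = TrialEvaluation(spec=spec)
    # detection vs ground truth, per (etype, side)
    for et, side in EVENT_STREAMS:
        r = gt.events.select(et, side)
        d = imu_events.select(et, side)
        m = match_events(r, d, max_gap)
        ev.gt_event_counts[(et, side)] = m.n_ref
        ev.imu_matched_counts[(et, side)] = len(m.pairs)
        mr = match_events(ref_events.select(et, side), d, max_gap)
        ev.event_errors_ref_vs_imu[(et, side)] = mr.errors_s.tolist()

    # phases: reference pipeline vs IMU pipeline
    try:
        imu_recs = cycles_and_phases(imu_events, tree_cfg)
        ref_recs = cycles_and_phases(ref_events, tree_cfg)
    except NoCyclesError:
        imu_recs, ref_recs = [], []
    ev.phase_errors, ev.phase_rel_errors = _phase_error_lists(
        ref_recs, imu_recs, max_gap)

    # per-cycle classification vs generator labels
    gt_starts = gt.cycle_starts[:-1]
    labels_by_start = list(zip(gt_starts, gt.labels))
    imu_by_start = {r.t_start: r.subtech for r in imu_recs}
    imu_starts = np.array(sorted(imu_by_start))
    ev.n_cycles_gt = len(labels_by_start)
    for t0, lab in labels_by_start:
        if imu_starts.size:
            j = int(np.argmin(np.abs(imu_starts - t0)))
            if abs(imu_starts[j] - t0) <= max_gap:
                if imu_by_start[float(imu_starts[j])] == lab:
                    ev.n_cycles_correct += 1
    return ev


@dataclass
class BatchResult:
    """Aggregate metrics over a batch of trials."""

    detection_pct: float
    sigma_mu_ms: dict                 # phase -> median intra-trial SD, ms
    sigma_mu_rel: dict                # phase -> median intra-trial SD, %
    classification_pct: float
    per_phase_summary: pd.DataFrame
    n_trials: int

    @property
    def worst_sigma_mu_ms(self) -> float:
        return max(self.sigma_mu_ms.values())

    @property
    def worst_sigma_mu_rel(self) -> float:
        return max(self.sigma_mu_rel.values())


def make_batch_specs(seed: int, n_per_technique: int = 10, n_cycles: int = 50,
                     **overrides) -> list[TrialSpec]:
    """Trial specs for a validation batch: ``n_per_technique`` trials of
    each sub-technique, child-seeded from one root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(3 * n_per_technique) % (2 ** 31)
    specs = []
    i = 0
    for tech in ("G2", "G3", "G4"):
        for _ in range(n_per_technique):
            specs.append(TrialSpec(subtech=tech, n_cycles=n_cycles,
                                   seed=int(children[i]), **overrides))
            i += 1
    return specs


def evaluate_batch(specs: list[TrialSpec],
                   det_cfg: DetectionConfig = DetectionConfig(),
                   tree_cfg: TreeConfig = TreeConfig()) -> BatchResult:
    """Simulate and evaluate a batch; pool per-trial statistics the way the
    validation design prescribes (intra-trial SD, inter-trial median)."""
    evals = [evaluate_trial(simulate_trial(s), det_cfg, tree_cfg)
             for s in specs]
    total_ref = sum(sum(e.gt_event_counts.values()) for e in evals)
    total_matched = sum(sum(e.imu_matched_counts.values()) for e in evals)

    sigma_mu_ms, sigma_mu_rel = {}, {}
    rows = []
    for phase in PHASES_POOLED:
        per_trial = [intra_trial_stats(e.phase_errors[phase]) for e in evals]
        per_trial_rel = [
            (float(np.mean(r)), float(np.std(r, ddof=1)))
            for r in (np.asarray(e.phase_rel_errors[phase]) for e in evals)
            if r.size >= 2]
        stats_ms = inter_trial_stats(per_trial)
        stats_rel = inter_trial_stats(per_trial_rel)   # already in %
        sigma_mu_ms[phase] = stats_ms["sigma_mu"]
        sigma_mu_rel[phase] = stats_rel["sigma_mu"]
        rows.append({"phase": phase, **{k: stats_ms[k] for k in
                                        ("b_mu", "b_sigma", "sigma_mu", "sigma_sigma")},
                     "sigma_mu_rel_pct": stats_rel["sigma_mu"]})
    n_gt = sum(e.n_cycles_gt for e in evals)
    n_ok = sum(e.n_cycles_correct for e in evals)
    return BatchResult(
        detection_pct=detection_rate(total_ref, total_matched),
        sigma_mu_ms=sigma_mu_ms,
        sigma_mu_rel=sigma_mu_rel,
        classification_pct=100.0 * n_ok / n_gt if n_gt else math.nan,
        per_phase_summary=pd.DataFrame(rows).set_index("phase"),
        n_trials=len(evals),
    )
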