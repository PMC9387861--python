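# Methods

This note documents the models, numerical choices and known limitations of
the package. It is written for a reader who wants to know *why* the code
does what it does, and what passing tests do and do not demonstrate.

## The detection problem

Ski skating is cyclic: each cycle contains two leg pushes (left and right
ski) and, depending on the sub-technique, one or two pole pushes performed
by both arms near-simultaneously. The quantities of interest are the
ground-contact events P_ON/P_OFF (poles) and S_ON/S_OFF (skis) and the
phase durations derived from them. The method detects these events from
four IMUs (256 Hz, 3-axis accelerometer + 3-axis gyroscope) on the wrists
and skis, and is validated against a marker-based detector operating on
vertical pole-tip and ski trajectories (200 Hz).

## Filtering: zero-phase by contract

Every filter in the package is a Butterworth run forward–backward
(`sosfiltfilt`), so no group delay is introduced — event *timing* is the
deliverable, and a causal filter would bias every detected time. The
consequence is that a stated cutoff applies per pass; the cascade is −6 dB
at the cutoff. Signals are odd-reflection padded by roughly three times
the impulse-response length (≈ 3·fs/cutoff samples, capped at the signal
length) because trials start and end mid-motion.

The filter chain constants (0.1 Hz high-pass for integration drift, 5 Hz
high-pass for the pole-release transient, 2 Hz low-pass for the leg-cycle
band, 1 m·s⁻² acceleration-peak prominence) live in `DetectionConfig`.
The search windows are the package's own choices, absent from the method's
published description, and are likewise config keys:

* `near_window_s = 0.15 s` — half-width of every "near this landmark"
  refinement window; below half the shortest phase duration at the fastest
  protocol speeds, so windows of adjacent landmarks cannot overlap.
* `anchor_prominence_deg = 5` — yaw-angle maxima below this prominence do
  not anchor an arm cycle (the angle swings tens of degrees in real
  poling).
* anchor spacing is clamped to [0.4 s, 4 s] (plausible cycle durations);
  of two anchors closer than the minimum the lesser-prominence one is
  dropped.
* `ski_off_tail_frac = 0.4` — the roll-angle minimum that seeds S_OFF is
  searched in the last 40 % of the leg cycle.

Two detector details deserve a note:

* *P_ON candidate validation.* The wrist rule is "first positive
  acceleration peak with prominence ≥ 1 after the yaw-angle maximum, then
  the last negative peak before it". A positive peak that has **no**
  negative peak between the anchor and itself cannot mark a plant (there
  is no deceleration apex before it); such candidates are skipped and the
  scan continues with the next positive peak. Only a cycle with no valid
  (negative, positive) peak sequence counts as a miss. Without this rule,
  marginal noise peaks right at the anchor silently deleted whole cycles.
* *Ski-cycle anchors* are positive-going zero crossings of the 2 Hz
  low-passed roll rate, accepted only if the rate visited a genuinely
  negative lobe (20 % of the signal's amplitude) since the previous
  crossing — a hysteresis that rejects edge artefacts and noise wiggles
  around zero.

A cycle with any missing constituent peak yields a **miss**, never an
extrapolated event; detected + missed = cycles per detector, and the
assembly step that enforces ON/OFF alternation counts every event it has
to drop as a further miss (of two consecutive OFFs the later is dropped;
of two consecutive ONs the earlier, so the newer complete pair survives).

## Reference detector

Contact runs are pre-selected where the vertical marker position is within
`margin_m` (default 3 mm ≈ 3 noise SDs) of the trial's 10 % height
quantile — the treadmill height is constant within a trial. Sub-25 ms
false gaps inside runs are closed and sub-25 ms runs removed. ON and OFF
are the maxima of the second derivative of vertical position within
±50 ms of the run start/end. Timestamps stay on the 200 Hz grid; no
sub-sample interpolation (the comparator's resolution is 5 ms).

The second difference at 200 Hz amplifies millimetre marker noise by fs²,
so the trajectory is low-passed at 20 Hz (2nd order, zero-phase) before
differentiation. This smoothing biases the curvature maximum of a
one-sided (flight-arc-to-plateau) junction ~15–20 ms toward the flight
side. The bias is systematic and near-identical for ON and OFF, so it
largely cancels in phase-duration differences and entirely drops out of
precision (SD-based) statistics; it does inflate the absolute bias b_μ of
individual events. Set `smooth_hz=None` for noiseless data, where the
unsmoothed curvature argmax recovers contact times to within 2 samples
(one sample of junction sidedness plus off-grid quantization).

## Cycles, phases, classification

Cycles are half-open intervals [left S_ON, next left S_ON); an event
exactly at a boundary belongs to the opening cycle. Left/right pole
events within 0.12 s merge to one action at their mean time (optimal
one-to-one pairing; unpaired events pass through). Phases follow the
standard definitions; a phase whose constituent events are missing is NaN,
never imputed, and a follow-up event farther than one cycle duration away
is treated as missing rather than bridging a detection gap. In cycles
with two pole actions (G3), P_CT/P_SW are the means over the defined
actions. `delay_Pon_Son` is the absolute shortest distance from a merged
plant to any ski contact of the cycle; `delay_Soff_Poff` is positive when
the pole leaves the ground after the ski.

The decision tree uses exactly the quantities the phase step computes:
2 merged plants → G3; 1 plant → G4 if `delay_Pon_Son ≤ 0.10 s` else G2;
0 plants or missing delay → NaN. The 0.10 s threshold sits between the
near-synchrony of G4 (≤ 30 ms by the kinematic definition) and the G2
offset (0.15–0.25 of a cycle, i.e. ≥ 0.17 s at the highest cycle rate).

## Agreement statistics

Matching is a one-to-one assignment maximizing the number of pairs within
`max_gap_s` (default: half the median reference cycle duration — beyond
that a candidate necessarily belongs to another cycle) and minimizing
total |error| among those; conflicting nearest-neighbour claims therefore
resolve in favour of the globally closer pairing. Errors are
`reference − IMU` (positive = IMU earlier). Intra-trial bias/precision
are mean and n−1 SD; inter-trial summaries are medians and IQRs
(linear-interpolation quantiles, noted because IQRs of small trial counts
are sensitive to the quantile rule). Kruskal–Wallis is tie-corrected with
the chi-square approximation; the DSCF post-hoc re-ranks each pair alone,
standardizes the tie-corrected rank sum and refers `W*·√2` to the
Studentized range with k groups and infinite df. The all-identical-data
omnibus case returns H = 0, p = 1 by contract.

## The synthetic generator

The generator reproduces the *temporal structure* of the techniques, not
their full biomechanics. Per cycle of duration T = 1/cycle_rate (defaults
G2 0.9 Hz, G3 0.8 Hz, G4 0.7 Hz, reflecting that the steep-uphill
technique cycles fastest): left S_ON at the cycle start, right S_ON at
T/2, ski contact 0.55·T per side, pole contact 0.30·T. G3 plants trail
each ski push by 27.5 ms (merged), G4's single plant trails the mid-cycle
push by the same, G2's single plant is offset 0.20·T from the nearest ski
contact. The two wrists straddle the nominal plant time by ±7.5 ms so the
merged action lands on it. Every event gets independent Gaussian jitter
(default SD 10 ms); cycles whose jitter breaks alternation are
rejection-resampled, and a spec whose jitter breaks more than 10 % of
cycles is rejected as infeasible. One warm-up and one cool-down cycle are
rendered but not scored, so scored events near the trial edges stay
detectable.

Waveforms carry exactly the features the detectors key on: a pchip yaw
angle peaking 12 ms before each P_ON (on the steep flank of the
deceleration lobe — with a flat approach, white accelerometer noise at
0.5 m·s⁻² SD would routinely exceed the 1 m·s⁻² prominence gate) and
bottoming at P_OFF; a sharp negative–positive acceleration doublet at
P_ON, a 10 ms transient at P_OFF, vertical spikes at S_ON/S_OFF (amplitudes
4–10 m·s⁻², within the realistic range for these impacts); a roll angle
peaking at S_ON and bottoming at S_OFF; gyro bias (default 0.5 deg·s⁻¹)
and white noise (2 deg·s⁻¹ gyro, 0.5 m·s⁻² accelerometer, 1 mm marker) on
top. Marker trajectories are flat contact plateaus joined C¹-continuously
by raised-cosine flight arcs (apex 0.05–0.25 m), whose curvature maxima
sit at the contact times by construction. An optional two-wheel mode adds
a smaller early spike before S_ON to emulate the roller-ski wheels landing
separately — the dominant real-world S_ON error source.

One root seed drives everything; per-stream child seeds derive from it via
`SeedSequence.spawn` in a fixed order (schedule; four marker tracks; four
IMUs), so a trial is bit-identical given its spec and partial regeneration
is reproducible.

**What passing tests show and what they do not.** The generator's events
and waveform features are mutually consistent by construction, noise is
white and stationary, and left/right arms act as one unit. Real
recordings add waveform variability between athletes and speeds,
non-Gaussian artefacts (pole vibration, wheel chatter), imperfect axis
alignment and soft-tissue motion. Passing the synthetic suite shows the
*pipeline logic* is correct and robust at realistic noise amplitudes; it
does not certify the published field accuracy on new athletes.

## Problem sizes

The validation batch is 30 trials (10 per technique) × 50 cycles — enough
cycles per trial for stable intra-trial SDs and enough trials for stable
medians, at a few seconds of runtime. The seed-robustness sweep re-runs
the four batch criteria for 100 seeds at a reduced size (one trial per
technique × 12 cycles per seed), the package's chosen compromise between
sweep breadth and per-seed cost; at that size single-event outliers can
fail an individual seed, which is why the sweep criterion is ≥ 95 of 100
seeds rather than all.

## Known limitations

* The reference detector's smoothing bias makes absolute event biases
  (b_μ) system-dependent; only precision-type conclusions should be drawn
  from the synthetic validation.
* The inter-system clock offset is modelled as known and constant
  (`imu_offset_s`); estimating it (e.g. from a dedicated synchronization
  plant) is out of scope.
* Free-gliding phases produce no detectable event by design; the method
  cannot time them.
* The decision tree covers G2/G3/G4 on straight terrain only; turning and
  the remaining gears are out of scope.
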