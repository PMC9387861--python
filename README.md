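# skate-events

Detection and validation of temporal events in cross-country ski skating
from wrist- and ski-mounted inertial measurement units (IMUs).

In ski skating, performance analysis builds on *inner-cycle temporal
parameters*: when each pole and each ski touches and leaves the ground.
From the four contact events — pole initial/final contact (P_ON, P_OFF) and
ski initial/final contact (S_ON, S_OFF) — one derives pole and ski contact
and swing times (P_CT, P_SW, S_CT, S_SW), the cycle time (S_CY, left-ski
contact to next left-ski contact), and the skating sub-technique ("gear")
G2/G3/G4 in use. Marker-based optical capture measures these precisely but
is confined to the lab; this package implements and validates a method that
needs only four light wearable sensors: one IMU per wrist and per ski.

## What the package does

* **IMU event detection** (`imu_detection`) — the core method:
  * *Wrist*: the yaw-axis angular velocity is integrated and high-passed
    (2nd order, 0.1 Hz) into a drift-free yaw angle whose maxima anchor the
    arm cycles. P_ON is the last negative yaw-acceleration peak before the
    first positive peak with prominence ≥ 1 m·s⁻² after the angle maximum;
    P_OFF is the most negative peak of the 5 Hz-high-passed yaw
    acceleration near the yaw-angle minimum.
  * *Ski*: the roll angular velocity low-passed at 2 Hz gives the leg-cycle
    rhythm; cycles are anchored at its positive-going zero crossings. S_ON
    is the maximal raw vertical-acceleration peak near the maximum of the
    drift-free roll angle; S_OFF the most negative vertical-acceleration
    peak near the late-cycle roll-angle minimum.
* **Reference detection** (`reference_detection`) — the marker-based
  comparator: ground-proximity masking of vertical pole-tip/ski
  trajectories, events at maxima of the second derivative of vertical
  position at contact-run boundaries.
* **Cycle analysis** (`cycle_analysis`) — cycles from left-ski contacts,
  left/right pole merging, inner-cycle phase durations and pole–ski delays.
* **Classification** (`classification`) — a decision tree on the merged
  pole-plant count and the pole–ski synchrony delay: two plants per cycle →
  G3; one synchronous plant → G4; one offset plant → G2; otherwise NaN.
* **Validation statistics** (`validation_stats`) — closest-event matching
  with miss/spurious accounting, intra-trial bias (mean error) and
  precision (SD of error), inter-trial medians and IQRs (b_μ, b_σ, σ_μ,
  σ_σ), relative (percent-of-phase) errors, Kruskal–Wallis and the
  Dwass–Steel–Critchlow–Fligner all-pairs post-hoc test. The error sign
  convention is `reference − IMU`: positive means the IMU detected the
  event earlier.
* **Synthetic trials** (`synthetic_data`) — a generator producing
  ground-truth event schedules for G2/G3/G4, marker trajectories and all
  four IMU streams with configurable sensor noise, gyro bias and
  stride-to-stride jitter, so the whole chain is testable end to end with a
  known answer key.

## Worked example

```bash
skate-events simulate --seed 5 --out trial/          # synthetic G3 trial
skate-events detect-imu  --imu-dir trial/    --out imu_events.json
skate-events detect-ref  --marker-dir trial/ --out ref_events.json
skate-events phases   --events imu_events.json --out cycles.csv
skate-events classify --cycles cycles.csv \
    --ground-truth trial/ground_truth_labels.csv --out labels.csv
skate-events validate --ref ref_events.json --imu imu_events.json \
    --cycles cycles.csv --out report/
```

A run with the default spec (G3, 50 cycles) prints, for example:

```
wrote trial (G3, 50 cycles) to trial
616 events written to imu_events.json (0 cycle-events missed)
631 reference events written to ref_events.json
50 cycles written to cycles.csv
50 cycles classified (majority G3, fraction correct 0.980) -> labels.csv
report written to report/ (majority technique G3)
```

`cycles.csv` holds one row per skiing cycle with S_CY, per-side S_CT/S_SW,
merged-pole P_CT/P_SW (seconds), the pole–ski delays and the assigned
sub-technique. `report/table1.csv` lists the reference event counts and
the percentage the IMU method detected; `report/table2.csv` the
bias/precision statistics per event type (ms).

The same chain is available as library calls
(`skate_events.pipeline.evaluate_batch` runs simulate → detect (both
systems) → phases → classify → statistics over a batch of trials).

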