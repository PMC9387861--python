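"""Sub-technique (gear) classification from temporal events.

The three main skating sub-techniques differ only in how poling actions
coordinate with the leg pushes:

* **G3** — a (double-)pole push with every leg push: two merged pole plants
  per cycle;
* **G4** — one symmetric pole push per cycle, synchronous with a ski plant;
* **G2** — one asymmetric pole push per cycle, offset from the ski plants.

A cycle is therefore classified by (i) the merged pole-plant count and
(ii) the pole–ski synchrony delay; anything else (no plants, missing
required events) falls into the NaN sink category.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import math

import numpy as np

from skate_events.cycle_analysis import CycleRecord
from skate_events.errors import InvalidParameterError

__all__ = ["TreeConfig", "classify_cycle", "classify_trial", "SUBTECHNIQUES"]

SUBTECHNIQUES = ("G2", "G3", "G4")


@dataclass(frozen=True)
class TreeConfig:
    """Decision-tree thresholds.

    ``sync_threshold_s`` separates a synchronous pole-ski plant (G4) from an
    offset one (G2); it sits between the near-zero synchrony of G4 and the
    0.15-0.25 cycle offset of G2.
    """

    sync_threshold_s: float = 0.10
    min_events_per_cycle: int = 2

    def __post_init__(self):
        if self.sync_threshold_s <= 0:
            raise InvalidParameterError("sync_threshold_s must be > 0")


def classify_cycle(rec: CycleRecord, pole_plants_in_cycle: int | None = None,
                   cfg: TreeConfig = TreeConfig()) -> str:
    """Assign G2/G3/G4 or NaN to one cycle.

    Two merged pole plants -> G3.  One plant -> G4 when the plant is
    synchronous with a ski contact (delay <= threshold), G2 otherwise.
    Zero plants, or a missing synchrony delay, -> NaN.
    """
    n = rec.n_pole_plants if pole_plants_in_cycle is None else pole_plants_in_cycle
    if n >= 2:
        return "G3"
    if n == 1:
        if math.isnan(rec.delay_Pon_Son):
            return "NaN"
        return "G4" if rec.delay_Pon_Son <= cfg.sync_threshold_s else "G2"
    return "NaN"


def classify_trial(records: list[CycleRecord],
                   ground_truth: list[str] | None = None,
                   cfg: TreeConfig = TreeConfig()) -> dict:
    """Per-cycle labels, trial majority label, and accuracy vs. ground truth.

    Returns a dict with ``labels`` (one per cycle), ``majority`` (ties and
    empty input -> 'NaN'), and, when ``ground_truth`` is given,
    ``fraction_correct`` and a ``confusion`` Counter of (truth, predicted)
    pairs.
    """
    if not records:
        raise InvalidParameterError("classify_trial needs at least one cycle")
    labels = [classify_cycle(r, cfg=cfg) for r in records]
    for r, lab in zip(records, labels):
        r.subtech = lab
    counts = Counter(labels)
    best = counts.most_common()
    if len(best) > 1 and best[0][1] == best[1][1]:
        majority = "NaN"
    else:
        majority = best[0][0]
    out = {"labels": labels, "majority": majority}
    if ground_truth is not None:
        if len(ground_truth) != len(labels):
            raise InvalidParameterError(
                "ground_truth length must match the number of cycles")
        correct = sum(1 for a, b in zip(ground_truth, labels) if a == b)
        out["fraction_correct"] = correct / len(labels)
        out["confusion"] = Counter(zip(ground_truth, labels))
    return out
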