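"""Method-agreement statistics: event matching, miss accounting,
bias/precision summaries, and between-technique rank tests.

Every IMU event is attributed to the closest reference event (one-to-one);
non-attributed reference events count as missed for the IMU method.  The
timing error is ``ref.time − imu.time``, so positive values mean the event
was detected *earlier* by the IMU.  Within a trial the bias is the mean
error and the precision the sample standard deviation; across trials the
median and interquartile range of those two quantities give the four
summary statistics b_μ, b_σ, σ_μ, σ_σ.  Between-technique differences are
tested with a tie-corrected Kruskal–Wallis omnibus test followed by the
Dwass–Steel–Critchlow–Fligner all-pairs post-hoc procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from skate_events.errors import InvalidParameterError
from skate_events.reference_detection import Event, EventSeries

__all__ = [
    "MatchResult", "match_events", "intra_trial_stats", "inter_trial_stats",
    "relative_phase_errors", "kruskal_wallis", "dscf_posthoc",
    "detection_rate",
]

log = logging.getLogger(__name__)


@dataclass
class MatchResult:
    """One-to-one attribution of IMU events to reference events.

    ``pairs`` holds (ref event, imu event, error_s = ref.time − imu.time).
    Conservation: |pairs| + |missed_ref| = ref count and
    |pairs| + |spurious_imu| = imu count.
    """

    pairs: list[tuple[Event, Event, float]] = field(default_factory=list)
    missed_ref: list[Event] = field(default_factory=list)
    spurious_imu: list[Event] = field(default_factory=list)

    @property
    def errors_s(self) -> np.ndarray:
        return np.array([e for _, _, e in self.pairs], dtype=float)

    @property
    def n_ref(self) -> int:
        return len(self.pairs) + len(self.missed_ref)

    @property
    def n_imu(self) -> int:
        return len(self.pairs) + len(self.spurious_imu)


def match_events(ref: EventSeries, imu: EventSeries,
                 max_gap_s: float) -> MatchResult:
    """Attribute each IMU event to its closest reference event.

    Attribution is the optimal one-to-one assignment that maximizes the
    number of pairs within ``max_gap_s`` and, among those, minimizes the
    total |error| (conflicting nearest-neighbour claims resolve in favour
    of the globally closer pairing).  Pairs further apart than ``max_gap_s``
    dissolve into missed/spurious.
    """
    if max_gap_s <= 0:
        raise InvalidParameterError("max_gap_s must be > 0")
    r_ev = list(ref.events)
    i_ev = list(imu.events)
    if not r_ev or not i_ev:
        return MatchResult(pairs=[], missed_ref=r_ev, spurious_imu=i_ev)
    rt = np.array([e.time for e in r_ev])
    it = np.array([e.time for e in i_ev])
    cost = np.abs(rt[:, None] - it[None, :])
    feasible = cost <= max_gap_s
    big = max_gap_s * (len(r_ev) + len(i_ev) + 1) + float(np.sum(cost)) + 1.0
    ri, ci = linear_sum_assignment(np.where(feasible, cost, big))
    pairs, used_r, used_i = [], set(), set()
    for i, j in zip(ri, ci):
        if feasible[i, j]:
            pairs.append((r_ev[i], i_ev[j], float(rt[i] - it[j])))
            used_r.add(i)
            used_i.add(j)
    return MatchResult(
        pairs=pairs,
        missed_ref=[e for k, e in enumerate(r_ev) if k not in used_r],
        spurious_imu=[e for k, e in enumerate(i_ev) if k not in used_i],
    )


def intra_trial_stats(errors_s) -> tuple[float, float] | None:
    """Per-trial bias (mean) and precision (n−1 standard deviation), in ms.

    Returns ``None`` (undefined-statistic marker) for fewer than two
    errors; such trials are excluded from pooling.
    """
    e = np.asarray(list(errors_s), dtype=float) * 1000.0
    e = e[np.isfinite(e)]
    if e.size < 2:
        log.info("intra_trial_stats: %d error(s), trial excluded", e.size)
        return None
    return float(np.mean(e)), float(np.std(e, ddof=1))


def inter_trial_stats(per_trial: list[tuple[float, float]]) -> dict:
    """Across-trial summary: b_mu/b_sigma = median/IQR of the per-trial
    biases, sigma_mu/sigma_sigma = median/IQR of the per-trial precisions.

    IQR is Q3 − Q1 with linear-interpolation quantiles.
    """
    per_trial = [p for p in per_trial if p is not None]
    if not per_trial:
        raise InvalidParameterError("inter_trial_stats needs >= 1 trial")
    biases = np.array([b for b, _ in per_trial])
    precs = np.array([s for _, s in per_trial])

    def iqr(x):
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)

    return {
        "b_mu": float(np.median(biases)),
        "b_sigma": iqr(biases),
        "sigma_mu": float(np.median(precs)),
        "sigma_sigma": iqr(precs),
        "n_trials": int(biases.size),
    }


def relative_phase_errors(phase_errors_s, phase_durations_s) -> np.ndarray:
    """Per-cycle errors as a percentage of the reference phase duration.

    Cycles with zero, negative or undefined duration are excluded (logged).
    """
    err = np.asarray(list(phase_errors_s), dtype=float)
    dur = np.asarray(list(phase_durations_s), dtype=float)
    if err.size != dur.size:
        raise InvalidParameterError("errors and durations must align")
    ok = np.isfinite(err) & np.isfinite(dur) & (dur > 0)
    if not ok.all():
        log.info("relative_phase_errors: excluded %d cycle(s) with "
                 "undefined or non-positive duration", int((~ok).sum()))
    return 100.0 * err[ok] / dur[ok]


def kruskal_wallis(groups: list) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k−1 df).

    All pooled values identical is a degenerate no-effect case: H = 0,
    p = 1.
    """
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 1 for a in arrs):
        raise InvalidParameterError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrs)
    if pooled.size < 3:
        raise InvalidParameterError("need >= 3 values in total")
    df = len(arrs) - 1
    if np.ptp(pooled) == 0:
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrs)
    return float(h), df, float(p)


def dscf_posthoc(groups: list, labels: list[str] | None = None) -> pd.DataFrame:
    """Dwass–Steel–Critchlow–Fligner all-pairs post-hoc test.

    Each pair of groups is re-ranked alone; the tie-corrected two-sample
    rank-sum statistic is standardized and referred (as ``W* · √2``) to the
    Studentized range distribution with k groups and infinite df.  Returns
    a DataFrame with columns group_a, group_b, W (standardized statistic)
    and p (two-sided).  Empty groups skip their pairs (logged).
    """
    arrs = [np.asarray(list(g), dtype=float) for g in groups]
    k = len(arrs)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[i], arrs[j]
            if a.size == 0 or b.size == 0:
                log.info("dscf_posthoc: empty group, pair (%s, %s) skipped",
                         labels[i], labels[j])
                continue
            n1, n2 = a.size, b.size
            pooled = np.concatenate([a, b])
            ranks = stats.rankdata(pooled)
            w = float(np.sum(ranks[n1:]))          # rank sum of group b
            n = n1 + n2
            mean_w = n2 * (n + 1) / 2.0
            _, counts = np.unique(pooled, return_counts=True)
            tie = float(np.sum(counts ** 3 - counts))
            var_w = (n1 * n2 / 12.0) * ((n + 1) - tie / (n * (n - 1)))
            if var_w <= 0:
                w_std = 0.0
            else:
                w_std = (w - mean_w) / math.sqrt(var_w)
            q = abs(w_std) * math.sqrt(2.0)
            p = float(stats.studentized_range.sf(q, k, np.inf))
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "W": w_std, "p": min(p, 1.0)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "W", "p"])


def detection_rate(ref_count: int, matched_count: int) -> float:
    """Percentage of reference events detected, ``100 · matched / ref``.

    ``ref_count == 0`` is undefined and returns NaN (rendered as '—' in
    reports).
    """
    if matched_count > ref_count:
        raise InvalidParameterError("matched count cannot exceed ref count")
    if ref_count == 0:
        return math.nan
    return 100.0 * matched_count / ref_count
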