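"""Tests for event matching and the bias/precision and rank statistics."""

import itertools
import math

import numpy as np
import pytest

from skate_events.errors import InvalidParameterError
from skate_events.reference_detection import Event, EventSeries
from skate_events.validation_stats import (
    detection_rate, dscf_posthoc, inter_trial_stats, intra_trial_stats,
    kruskal_wallis, match_events, relative_phase_errors)


def evs(times, etype="S_ON", side="left", source="reference"):
    return EventSeries([Event(t, etype, side, source) for t in times])


def brute_force_match(ref, imu, max_gap):
    """Exhaustive optimal assignment: maximize pairs within the gap, then
    minimize total |error|; returns the set of (ref_idx, imu_idx) pairs."""
    nr, ni = len(ref), len(imu)
    for k in range(min(nr, ni), -1, -1):
        best_cost, best = math.inf, None
        for ri in itertools.combinations(range(nr), k):
            for ij in itertools.permutations(range(ni), k):
                if all(abs(ref[a] - imu[b]) <= max_gap
                       for a, b in zip(ri, ij)):
                    cost = sum(abs(ref[a] - imu[b]) for a, b in zip(ri, ij))
                    if cost < best_cost:
                        best_cost, best = cost, set(zip(ri, ij))
        if best is not None:
            return best
    return set()


class TestMatchEvents:
    def test_two_clean_pairs(self):
        m = match_events(evs([1.0, 2.0]), evs([1.02, 1.98], source="imu"), 0.5)
        assert sorted(np.round(m.errors_s, 6)) == [-0.02, 0.02]
        assert not m.missed_ref and not m.spurious_imu

    def test_unmatched_reference_is_missed(self):
        m = match_events(evs([1.0, 2.0]), evs([1.02], source="imu"), 0.5)
        assert len(m.pairs) == 1
        assert [e.time for e in m.missed_ref] == [2.0]

    def test_empty_reference_all_spurious(self):
        m = match_events(evs([]), evs([1.0, 2.0], source="imu"), 0.5)
        assert not m.pairs and len(m.spurious_imu) == 2

    def test_conservation_identities(self, rng):
        for _ in range(50):
            rt = np.sort(rng.uniform(0, 10, size=rng.integers(0, 8)))
            it = np.sort(rng.uniform(0, 10, size=rng.integers(0, 8)))
            rt = rt[np.concatenate([[True], np.diff(rt) > 0.06])] if rt.size else rt
            it = it[np.concatenate([[True], np.diff(it) > 0.06])] if it.size else it
            m = match_events(evs(rt), evs(it, source="imu"), 0.4)
            assert len(m.pairs) + len(m.missed_ref) == rt.size
            assert len(m.pairs) + len(m.spurious_imu) == it.size

    def test_matches_exhaustive_assignment_oracle(self, rng):
        for _ in range(100):
            nr, ni = rng.integers(0, 6), rng.integers(0, 6)
            rt = np.sort(rng.uniform(0, 4, size=nr))
            it = np.sort(rng.uniform(0, 4, size=ni))
            if rt.size > 1 and np.any(np.diff(rt) < 0.06):
                continue
            if it.size > 1 and np.any(np.diff(it) < 0.06):
                continue
            m = match_events(evs(rt), evs(it, source="imu"), 0.5)
            oracle = brute_force_match(list(rt), list(it), 0.5)
            got = {(list(rt).index(r.time), list(it).index(i.time))
                   for r, i, _ in m.pairs}
            # pair count always agrees; the pairing itself agrees up to
            # cost ties, so compare total cost
            assert len(got) == len(oracle)
            cost = sum(abs(rt[a] - it[b]) for a, b in got)
            cost_oracle = sum(abs(rt[a] - it[b]) for a, b in oracle)
            assert cost == pytest.approx(cost_oracle)

    def test_pairs_beyond_gap_dissolve(self):
        m = match_events(evs([1.0]), evs([2.0], source="imu"), 0.5)
        assert not m.pairs
        assert len(m.missed_ref) == 1 and len(m.spurious_imu) == 1


class TestIntraInterTrialStats:
    def test_mean_and_sample_sd(self):
        bias, prec = intra_trial_stats([-0.010, -0.020, -0.030])
        assert bias == pytest.approx(-20.0)
        assert prec == pytest.approx(10.0)

    def test_identical_errors_zero_precision(self):
        bias, prec = intra_trial_stats([0.005, 0.005, 0.005])
        assert prec == 0.0

    def test_single_error_is_undefined(self):
        assert intra_trial_stats([0.004]) is None

    def test_sampling_distribution_recovery(self, rng):
        # draws echoing a typical pole-contact error distribution
        draws = rng.normal(-0.022, 0.007, size=1000)
        bias, prec = intra_trial_stats(draws)
        assert bias == pytest.approx(-22.0, abs=0.7)
        assert prec == pytest.approx(7.0, abs=0.5)

    def test_inter_trial_median_and_iqr(self):
        out = inter_trial_stats([(-10.0, 5.0), (-20.0, 10.0), (-30.0, 15.0)])
        assert out["b_mu"] == -20.0
        assert out["sigma_mu"] == 10.0
        assert out["b_sigma"] == 10.0
        assert out["sigma_sigma"] == 5.0

    def test_single_trial_zero_iqr(self):
        out = inter_trial_stats([(-5.0, 3.0)])
        assert out["b_sigma"] == 0.0 and out["sigma_sigma"] == 0.0

    def test_matches_interpolated_quantile_oracle(self, rng):
        biases = rng.normal(size=200)
        precs = np.abs(rng.normal(size=200))

        def q(x, p):
            # sort-based linear-interpolation quantile
            xs = np.sort(x)
            h = (len(xs) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        out = inter_trial_stats(list(zip(biases, precs)))
        assert out["b_mu"] == pytest.approx(q(biases, 0.5))
        assert out["b_sigma"] == pytest.approx(q(biases, 0.75) - q(biases, 0.25))
        assert out["sigma_mu"] == pytest.approx(q(precs, 0.5))

    def test_none_trials_are_excluded(self):
        out = inter_trial_stats([None, (-4.0, 2.0), None])
        assert out["n_trials"] == 1


class TestRelativePhaseErrors:
    def test_simple_percentage(self):
        out = relative_phase_errors([0.024], [1.2])
        assert out[0] == pytest.approx(2.0)

    def test_zero_error_zero_percent(self):
        assert relative_phase_errors([0.0], [0.8])[0] == 0.0

    def test_undefined_durations_excluded(self):
        out = relative_phase_errors([0.01, 0.01, 0.01], [1.0, 0.0, math.nan])
        assert len(out) == 1

    def test_equals_elementwise_oracle(self, rng):
        err = rng.normal(0, 0.02, size=300)
        dur = rng.uniform(0.5, 1.5, size=300)
        out = relative_phase_errors(err, dur)
        assert np.max(np.abs(out - 100.0 * err / dur)) < 1e-12


def kw_oracle(groups):
    """Textbook tie-corrected Kruskal-Wallis H."""
    pooled = np.concatenate(groups)
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    rank_vals = np.empty(n)
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        rank_vals[i:j] = (i + j + 1) / 2.0
        i = j
    ranks[order] = rank_vals
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    return h / (1.0 - tie / (n ** 3 - n)) if tie else h


class TestKruskalWallis:
    def test_toy_example_hand_ranks(self):
        h, df, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        assert df == 2

    def test_identical_groups_no_effect(self):
        h, df, p = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert h == 0.0 and p == 1.0

    def test_random_groups_match_textbook_oracle(self, rng):
        for _ in range(20):
            groups = [rng.normal(size=rng.integers(3, 12)) for _ in range(3)]
            h, _, _ = kruskal_wallis(groups)
            assert h == pytest.approx(kw_oracle(groups), abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        groups = [rng.uniform(0.1, 5, size=8) for _ in range(3)]
        h1, _, p1 = kruskal_wallis(groups)
        h2, _, p2 = kruskal_wallis([np.log(g) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidParameterError):
            kruskal_wallis([[1.0, 2.0], []])


def dscf_pair_oracle(a, b, k):
    """From-scratch standardized two-sample rank statistic for one pair."""
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)
    n = n1 + n2
    order = np.argsort(pooled, kind="stable")
    sorted_vals = pooled[order]
    ranks = np.empty(n)
    i = 0
    rv = np.empty(n)
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        rv[i:j] = (i + j + 1) / 2.0
        i = j
    ranks[order] = rv
    w = ranks[n1:].sum()
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts ** 3 - counts)
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    return (w - n2 * (n + 1) / 2.0) / math.sqrt(var)


class TestDSCF:
    def test_identical_groups_p_one(self):
        g = [1.0, 2.0, 3.0, 4.0]
        table = dscf_posthoc([g, list(g)])
        assert table.loc[0, "W"] == pytest.approx(0.0)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_well_separated_groups_all_significant(self, rng):
        groups = [rng.normal(0, 1, 20), rng.normal(10, 1, 20),
                  rng.normal(20, 1, 20)]
        table = dscf_posthoc(groups)
        assert len(table) == 3
        assert (table["p"] < 0.001).all()

    def test_pairwise_reranking_matches_oracle(self, rng):
        groups = [rng.normal(size=9), rng.normal(size=7), rng.normal(size=11)]
        table = dscf_posthoc(groups, labels=["a", "b", "c"])
        for _, row in table.iterrows():
            i = ["a", "b", "c"].index(row["group_a"])
            j = ["a", "b", "c"].index(row["group_b"])
            w = dscf_pair_oracle(groups[i], groups[j], 3)
            assert row["W"] == pytest.approx(w, abs=1e-9)

    def test_empty_group_pairs_skipped(self):
        table = dscf_posthoc([[1.0, 2.0], [], [3.0, 4.0]])
        assert len(table) == 1


class TestDetectionRate:
    def test_printed_style_rounding(self):
        assert round(detection_rate(25381, 25356), 1) == 99.9

    def test_bounds(self):
        assert detection_rate(10, 10) == 100.0
        assert detection_rate(10, 0) == 0.0
        assert math.isnan(detection_rate(0, 0))

    def test_matched_over_ref_rejected(self):
        with pytest.raises(InvalidParameterError):
            detection_rate(5, 6)


class TestParameterRecovery:
    """Injected-offset and jitter recovery through the matching + pooling
    chain (the validation design's own calibration)."""

    def test_constant_offset_appears_as_negative_bias(self, rng):
        # imu detects delta late -> error = ref - imu = -delta
        delta = 0.025
        per_trial = []
        for _ in range(30):
            ref_t = np.arange(50) * 1.25 + rng.uniform(0, 0.1)
            imu_t = ref_t + delta + rng.normal(0, 0.004, size=50)
            m = match_events(evs(ref_t), evs(imu_t, source="imu"), 0.6)
            per_trial.append(intra_trial_stats(m.errors_s))
        out = inter_trial_stats(per_trial)
        assert out["b_mu"] == pytest.approx(-delta * 1000, abs=2.0)

    def test_jitter_sd_recovered_as_precision(self, rng):
        s = 0.010
        per_trial = []
        for _ in range(30):
            ref_t = np.arange(50) * 1.25
            imu_t = ref_t + rng.normal(0, s, size=50)
            m = match_events(evs(ref_t), evs(imu_t, source="imu"), 0.6)
            per_trial.append(intra_trial_stats(m.errors_s))
        out = inter_trial_stats(per_trial)
        # reference exact, one jittered stream: sigma_mu recovers s
        assert out["sigma_mu"] == pytest.approx(s * 1000, rel=0.10)

    def test_double_jitter_recovers_sqrt2_inflation(self, rng):
        s = 0.010
        per_trial = []
        for _ in range(30):
            base = np.arange(50) * 1.25
            ref_t = base + rng.normal(0, s, size=50)
            imu_t = base + rng.normal(0, s, size=50)
            m = match_events(evs(np.sort(ref_t)),
                             evs(np.sort(imu_t), source="imu"), 0.6)
            per_trial.append(intra_trial_stats(m.errors_s))
        out = inter_trial_stats(per_trial)
        assert out["sigma_mu"] == pytest.approx(s * 1000 * math.sqrt(2), rel=0.10)
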