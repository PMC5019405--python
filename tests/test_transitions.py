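"""Approach detection and transition statistics on synthetic overlap traces."""

import numpy as np
import pytest

from hiermem import (
    ApproachSequence,
    approaches_from_overlaps,
    category_bias,
    transition_stats,
)


def _overlaps_from_episodes(n_times, n_targets, episodes):
    """Build an overlap matrix from (start, stop, target, peak) episodes."""
    O = np.zeros((n_times, n_targets))
    for start, stop, target, peak in episodes:
        seg = np.linspace(0.51, peak, stop - start)
        O[start:stop, target] = np.concatenate(
            [seg[: (stop - start + 1) // 2], seg[::-1][(stop - start) // 2 + 1:]]
        )[: stop - start]
    return O


def test_single_episode_peak_time_and_target():
    times = np.arange(11, dtype=float)
    O = np.zeros((11, 4))
    O[3:8, 2] = [0.52, 0.6, 0.9, 0.7, 0.55]  # peak at t = 5
    seq = approaches_from_overlaps(times, O, threshold=0.5)
    np.testing.assert_array_equal(seq.targets, [2])
    np.testing.assert_array_equal(seq.times, [5.0])


def test_highest_overlap_wins_simultaneous_targets():
    times = np.arange(5, dtype=float)
    O = np.zeros((5, 8))
    O[2, 3] = 0.6
    O[2, 7] = 0.8  # both above threshold; 7 is higher
    seq = approaches_from_overlaps(times, O, threshold=0.5)
    np.testing.assert_array_equal(seq.targets, [7])


def test_no_suprathreshold_episodes_gives_empty_sequence():
    seq = approaches_from_overlaps(np.arange(6, dtype=float),
                                   np.full((6, 3), 0.4), threshold=0.5)
    assert len(seq) == 0


def test_consecutive_same_target_episodes_merge():
    times = np.arange(12, dtype=float)
    O = np.zeros((12, 3))
    O[1:3, 1] = [0.6, 0.55]   # episode on target 1
    O[5:7, 1] = [0.8, 0.6]    # again target 1: merged, not a self-transition
    O[9:11, 2] = [0.7, 0.55]
    seq = approaches_from_overlaps(times, O, threshold=0.5)
    np.testing.assert_array_equal(seq.targets, [1, 2])
    np.testing.assert_array_equal(seq.times, [5.0, 9.0])  # peak of merged visit


def test_entry_timestamp_mode():
    times = np.arange(10, dtype=float)
    O = np.zeros((10, 2))
    O[4:8, 0] = [0.52, 0.6, 0.95, 0.6]
    seq = approaches_from_overlaps(times, O, threshold=0.5, timestamp="entry")
    np.testing.assert_array_equal(seq.times, [4.0])


def test_alternating_sequence_statistics():
    seq = ApproachSequence(times=[0.0, 1.0, 2.0, 3.0],
                           targets=[0, 1, 0, 1], threshold=0.5)
    stats = transition_stats(seq, km=4, m=2)
    assert stats.P[1, 0] == pytest.approx(1.0)
    assert stats.P[0, 1] == pytest.approx(1.0)
    assert stats.T[1, 0] == pytest.approx(1.0)
    assert stats.T[0, 1] == pytest.approx(1.0)
    assert stats.n_transitions == 3


def test_hand_enumerated_sequence():
    """alpha = (0, 1, 7, 0) at t = (0, 2, 5, 9), K*M = 12, M = 6."""
    seq = ApproachSequence(times=[0.0, 2.0, 5.0, 9.0],
                           targets=[0, 1, 7, 0], threshold=0.5)
    stats = transition_stats(seq, km=12, m=6)
    assert stats.P[1, 0] == pytest.approx(1.0)
    assert stats.P[7, 1] == pytest.approx(1.0)
    assert stats.P[0, 7] == pytest.approx(1.0)
    assert stats.T[1, 0] == pytest.approx(2.0)
    assert stats.T[7, 1] == pytest.approx(3.0)
    assert stats.T[0, 7] == pytest.approx(4.0)
    # category level: 0->1 stays in category 0; 1->7 crosses to category 1
    assert stats.P_cat[0, 0] == pytest.approx(0.5)
    assert stats.P_cat[1, 0] == pytest.approx(0.5)
    assert stats.P_cat[0, 1] == pytest.approx(1.0)
    assert stats.T_cat[0, 1] == pytest.approx(4.0)


def test_column_normalisation_and_zero_diagonal(rng):
    targets = rng.integers(0, 12, 400)
    # remove immediate repeats (merged by construction in real sequences)
    keep = np.r_[True, np.diff(targets) != 0]
    targets = targets[keep]
    times = np.cumsum(rng.uniform(0.5, 3.0, len(targets)))
    stats = transition_stats(
        ApproachSequence(times=times, targets=targets, threshold=0.5), 12, 3
    )
    visited = stats.counts.sum(axis=0) > 0
    np.testing.assert_allclose(
        np.nansum(stats.P[:, visited], axis=0), 1.0, atol=1e-12
    )
    assert np.all(np.diag(stats.P) == 0.0)
    np.testing.assert_allclose(
        np.nansum(stats.P_cat, axis=0), 1.0, atol=1e-12
    )
    # mean transition times are at least the smallest gap
    assert np.nanmin(stats.T) >= 0.5 - 1e-12


def test_category_aggregation_consistent_with_direct_counts(rng):
    targets = rng.integers(0, 12, 300)
    targets = targets[np.r_[True, np.diff(targets) != 0]]
    times = np.cumsum(rng.uniform(0.1, 2.0, len(targets)))
    m = 4
    stats = transition_stats(
        ApproachSequence(times=times, targets=targets, threshold=0.5), 12, m
    )
    cats = targets // m
    k = 3
    direct = np.zeros((k, k))
    for a, b in zip(cats[1:], cats[:-1]):
        direct[a, b] += 1
    np.testing.assert_allclose(
        stats.P_cat, np.where(direct.sum(0) > 0, direct / direct.sum(0), np.nan)
    )


def test_uniform_random_sequence_category_bias(rng):
    """Uniform target visits: within-category P' ~ (M-1)/(KM-1)."""
    km, m = 36, 6
    targets = rng.integers(0, km, 20000)
    targets = targets[np.r_[True, np.diff(targets) != 0]]
    times = np.cumsum(np.ones(len(targets)))
    stats = transition_stats(
        ApproachSequence(times=times, targets=targets, threshold=0.5), km, m
    )
    bias = category_bias(stats)
    assert bias.within_p == pytest.approx((m - 1) / (km - 1), abs=0.02)
    assert bias.cross_p == pytest.approx(
        (1 - (m - 1) / (km - 1)) / 5, abs=0.02
    )


def test_block_sequence_within_only():
    seq = ApproachSequence(times=[0.0, 1.0, 2.0, 3.0],
                           targets=[0, 1, 2, 0], threshold=0.5)
    stats = transition_stats(seq, km=6, m=3)
    bias = category_bias(stats)
    assert bias.within_p == pytest.approx(1.0)
    assert bias.cross_p == pytest.approx(0.0)


def test_short_sequence_warns():
    seq = ApproachSequence(times=[1.0], targets=[3], threshold=0.5)
    with pytest.warns(UserWarning):
        stats = transition_stats(seq, km=6, m=3)
    assert stats.n_transitions == 0
    assert np.isnan(stats.P).all() or (np.nansum(stats.P) == 0)


def test_oracle_equivalence_on_random_traces(rng):
    """Naive per-sample rescan reproduces the vectorised visit sequence."""

    def naive(times, O, thr):
        visits = []
        in_episode = False
        ep = []
        for idx in range(len(times)):
            if O[idx].max() > thr:
                in_episode = True
                ep.append(idx)
            elif in_episode:
                visits.append(ep)
                ep, in_episode = [], False
        if ep:
            visits.append(ep)
        out_t, out_a, out_peak = [], [], []
        for ep in visits:
            sub = O[ep]
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            t, a, peak = times[ep[i]], j, sub[i, j]
            if out_a and out_a[-1] == a:
                if peak > out_peak[-1]:
                    out_t[-1], out_peak[-1] = t, peak
            else:
                out_t.append(t)
                out_a.append(a)
                out_peak.append(peak)
        return np.asarray(out_t), np.asarray(out_a)

    for _ in range(100):
        n_t = int(rng.integers(5, 80))
        n_targets = int(rng.integers(2, 6))
        O = rng.uniform(-0.2, 0.75, (n_t, n_targets))
        times = np.cumsum(rng.uniform(0.1, 1.0, n_t))
        seq = approaches_from_overlaps(times, O, threshold=0.5)
        t_ref, a_ref = naive(times, O, 0.5)
        np.testing.assert_array_equal(seq.targets, a_ref)
        np.testing.assert_allclose(seq.times, t_ref)
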