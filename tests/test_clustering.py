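"""Similarity, UPGMA cluster counting (with a brute-force oracle) and PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hiermem import (
    SimilarityMatrix,
    Trajectory,
    count_clusters,
    mean_activity,
    pc_projection,
    similarity,
    similarity_deviation,
    target_similarity_matrix,
)
from hiermem.patterns import PatternSpec, generate_pattern_set


def _traj(states, stride=1.0):
    states = np.atleast_2d(np.asarray(states, dtype=float))
    return Trajectory(
        times=np.arange(len(states), dtype=float) * stride,
        states=states,
        gamma=0.0,
        record_stride=stride,
    )


# ------------------------------------------------------------ mean activity

def test_mean_activity_constant_and_oscillation():
    const = np.tile([0.3, -0.5], (11, 1))
    ma = mean_activity(_traj(const), transient=2.0, window=8.0)
    np.testing.assert_allclose(ma.xbar, [0.3, -0.5])
    osc = np.outer((-1.0) ** np.arange(20), [0.8, 0.1])
    ma = mean_activity(_traj(osc), transient=0.0, window=20.0)
    np.testing.assert_allclose(ma.xbar, 0.0, atol=0.05)


# --------------------------------------------------------------- similarity

def test_similarity_trivial_cases(rng):
    v = rng.uniform(-1, 1, 30)
    assert similarity(v, v) == pytest.approx(1.0)
    assert similarity(v, -v) == pytest.approx(-1.0)
    a = np.array([1.0, 0.0, 0.0])
    b = np.array([0.0, 1.0, 0.0])
    assert similarity(a, b) == pytest.approx(0.0)


def test_similarity_zero_vector_rejected():
    with pytest.raises(ValueError):
        similarity(np.zeros(4), np.ones(4))


def test_similarity_matrix_structure_and_deviation():
    ps = generate_pattern_set(PatternSpec(seed=8))
    sm = target_similarity_matrix(ps)
    assert np.allclose(sm.S, sm.S.T)
    np.testing.assert_allclose(np.diag(sm.S), 1.0)
    assert np.abs(sm.S).max() <= 1.0
    dev = similarity_deviation(sm, sm)
    np.testing.assert_allclose(dev, 0.0)


def test_similarity_matrix_validation():
    with pytest.raises(ValueError):
        SimilarityMatrix(S=np.array([[1.0, 0.5], [0.2, 1.0]]), gamma=0.0)


# ----------------------------------------------------------- UPGMA counting

def test_two_tight_pairs_give_two_clusters():
    # within-pair distance 0.05, cross-pair 0.9; cut at 0.3
    S = np.array(
        [
            [1.0, 0.95, 0.1, 0.1],
            [0.95, 1.0, 0.1, 0.1],
            [0.1, 0.1, 1.0, 0.95],
            [0.1, 0.1, 0.95, 1.0],
        ]
    )
    tree = count_clusters(S, threshold=0.3)
    assert tree.n_clusters == 2
    labels = tree.labels
    assert labels[0] == labels[1] and labels[2] == labels[3]
    assert labels[0] != labels[2]


def test_threshold_extremes(rng):
    X = rng.normal(size=(8, 5))
    S = X @ X.T / np.outer(*(2 * [np.linalg.norm(X, axis=1)]))
    np.fill_diagonal(S, 1.0)
    D = 1.0 - S
    off = D[~np.eye(8, dtype=bool)]
    assert count_clusters(S, threshold=off.min() * 0.5).n_clusters == 8
    assert count_clusters(S, threshold=2.5).n_clusters == 1


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), thr_lo=st.floats(0.01, 0.5))
def test_cluster_count_monotone_in_threshold(seed, thr_lo):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(10, 4))
    S = X @ X.T / np.outer(*(2 * [np.linalg.norm(X, axis=1)]))
    np.fill_diagonal(S, 1.0)
    n_lo = count_clusters(S, threshold=thr_lo).n_clusters
    n_hi = count_clusters(S, threshold=thr_lo + 0.5).n_clusters
    assert n_hi <= n_lo


def _brute_force_upgma(D):
    """O(n^3) group-average agglomeration; returns the merge heights."""
    clusters = {i: [i] for i in range(len(D))}
    heights = []
    next_id = len(D)
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights.append(d)
        next_id += 1
    return np.asarray(heights)


@settings(max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 12))
def test_upgma_matches_brute_force(seed, n):
    rng = np.random.default_rng(seed)
    D = rng.uniform(0.05, 1.0, (n, n))
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    tree = count_clusters(1.0 - D, threshold=0.3)
    np.testing.assert_allclose(
        np.sort(tree.linkage[:, 2]), np.sort(_brute_force_upgma(D)), atol=1e-9
    )
    assert (np.diff(tree.linkage[:, 2]) >= -1e-12).all()  # monotone merges


def test_identical_responses_collapse_to_one_cluster():
    S = np.ones((6, 6))
    assert count_clusters(S, threshold=0.3).n_clusters == 1


# ----------------------------------------------------------------- PCA part

def test_pca_line_captures_all_variance(rng):
    direction = rng.normal(size=5)
    coeffs = rng.normal(size=40)
    states = np.outer(coeffs, direction)
    res = pc_projection([_traj(states)], n_components=2)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)
    # orthonormal basis
    np.testing.assert_allclose(res.components @ res.components.T, np.eye(2),
                               atol=1e-10)


def test_pca_full_reconstruction(rng):
    states = rng.uniform(-1, 1, (30, 6))
    res = pc_projection([_traj(states)], n_components=6)
    recon = res.projections[0] @ res.components + res.mean
    np.testing.assert_allclose(recon, states, atol=1e-10)


def test_pca_sign_convention_and_pattern_projection(rng):
    states = rng.uniform(-1, 1, (50, 8))
    pats = rng.choice([-1.0, 1.0], (3, 8))
    res = pc_projection([_traj(states)], n_components=3, patterns=pats)
    for c in res.components:
        assert c[np.argmax(np.abs(c))] > 0
    assert res.pattern_projections.shape == (3, 3)


def test_pca_too_many_components(rng):
    with pytest.raises(ValueError):
        pc_projection([_traj(rng.uniform(-1, 1, (10, 4)))], n_components=5)
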