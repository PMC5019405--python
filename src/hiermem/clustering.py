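"""Similarity and hierarchical clustering of evoked activity patterns.

For each stored input mu the network is driven at strength gamma and the
temporal mean activity x-bar_mu is computed.  The cosine similarity

    S_mu_nu = sum_i xbar_i,mu xbar_i,nu / (|xbar_mu| |xbar_nu|)

(no mean-centering) compares responses to different inputs; agglomerative
clustering with group-average (UPGMA) linkage on the distance D = 1 - S,
cut at a fixed threshold, counts how many distinguishable response groups
the network produces at that input strength.  A PCA projection of pooled
trajectories provides the low-dimensional pictures of the state space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .dynamics import SimulationConfig, Trajectory, random_initial_state, simulate

if TYPE_CHECKING:  # pragma: no cover
    from .learning import TrainedNetwork
    from .patterns import PatternSet

__all__ = [
    "MeanActivity",
    "SimilarityMatrix",
    "ClusterTree",
    "ProjectionResult",
    "mean_activity",
    "similarity",
    "similarity_matrix",
    "target_similarity_matrix",
    "similarity_deviation",
    "count_clusters",
    "cluster_count_vs_strength",
    "pc_projection",
]


@dataclass
class MeanActivity:
    """Per-neuron temporal mean activity under one input."""

    xbar: np.ndarray
    mu: int | None
    gamma: float
    transient: float
    window: float


def mean_activity(traj: Trajectory, transient: float, window: float) -> MeanActivity:
    """Temporal mean state over ``window`` unit time after ``transient``."""
    return MeanActivity(
        xbar=traj.window(transient, window).mean(axis=0),
        mu=traj.mu,
        gamma=traj.gamma,
        transient=transient,
        window=window,
    )


def _as_vector(a) -> np.ndarray:
    v = np.asarray(a.xbar if isinstance(a, MeanActivity) else a, dtype=np.float64)
    if v.ndim != 1:
        raise ValueError("expected a 1-D activity vector")
    return v


def similarity(a, b) -> float:
    """Cosine similarity of two mean-activity vectors (no centering)."""
    va, vb = _as_vector(a), _as_vector(b)
    if va.shape != vb.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(va @ vb / (na * nb))


@dataclass
class SimilarityMatrix:
    """Pairwise cosine similarities of evoked mean activities at one gamma."""

    S: np.ndarray
    gamma: float
    transient: float = 100.0
    window: float = 400.0

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=np.float64)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("S must be square")
        if not np.allclose(S, S.T, atol=1e-10):
            raise ValueError("S must be symmetric")
        self.S = S

    @property
    def n(self) -> int:
        return self.S.shape[0]


def _cosine_matrix(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        raise ValueError("zero mean-activity vector; similarity undefined")
    S = (X @ X.T) / np.outer(norms, norms)
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 1.0)
    return np.clip(S, -1.0, 1.0)


def similarity_matrix(
    tn: "TrainedNetwork",
    ps: "PatternSet",
    gamma: float,
    transient: float = 100.0,
    window: float = 400.0,
    seed: int = 0,
) -> SimilarityMatrix:
    """Simulate all K*M evoked runs at ``gamma`` and compare mean activities.

    Each run starts from its own random initial state derived from ``seed``.
    """
    cfg = SimulationConfig(
        duration=transient + window, dt=tn.config.dt, transient=transient
    )
    seeds = np.random.SeedSequence(seed).spawn(ps.n_assoc)
    X = np.empty((ps.n_assoc, ps.spec.n))
    for mu in range(ps.n_assoc):
        x0 = random_initial_state(ps.spec.n, np.random.default_rng(seeds[mu]))
        traj = simulate(tn.network, ps.inputs[mu], gamma, x0, cfg, mu=mu)
        X[mu] = traj.window(transient, window).mean(axis=0)
    return SimilarityMatrix(S=_cosine_matrix(X), gamma=gamma, transient=transient, window=window)


def target_similarity_matrix(ps: "PatternSet", which: str = "targets") -> SimilarityMatrix:
    """Cosine similarities between the stored patterns themselves."""
    X = getattr(ps, which).astype(np.float64)
    return SimilarityMatrix(S=_cosine_matrix(X), gamma=float("nan"))


def similarity_deviation(evoked: SimilarityMatrix, reference: SimilarityMatrix) -> np.ndarray:
    """Element-wise S_activity - S_reference (e.g. versus target similarity)."""
    if evoked.n != reference.n:
        raise ValueError("matrices must have equal size")
    return evoked.S - reference.S


@dataclass
class ClusterTree:
    """Group-average dendrogram of D = 1 - S with a fixed cut."""

    linkage: np.ndarray
    threshold: float
    n_clusters: int
    labels: np.ndarray


def count_clusters(sim: SimilarityMatrix | np.ndarray, threshold: float = 0.3) -> ClusterTree:
    """UPGMA clustering on D = 1 - S, cut at distance ``threshold``.

    Returns the scipy linkage matrix, the flat cluster labels and the number
    of clusters obtained when no merge above the threshold is accepted.
    """
    S = sim.S if isinstance(sim, SimilarityMatrix) else np.asarray(sim, dtype=np.float64)
    if S.ndim != 2 or S.shape[0] != S.shape[1] or not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("similarity matrix must be square and symmetric")
    D = np.clip(1.0 - S, 0.0, None)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(0.5 * (D + D.T), checks=False), method="average")
    labels = fcluster(Z, t=threshold, criterion="distance")
    return ClusterTree(
        linkage=Z,
        threshold=threshold,
        n_clusters=int(labels.max()),
        labels=labels,
    )


def cluster_count_vs_strength(
    tn: "TrainedNetwork",
    ps: "PatternSet",
    gamma_grid: np.ndarray,
    threshold: float = 0.3,
    transient: float = 100.0,
    window: float = 400.0,
    seed: int = 0,
) -> list[tuple[float, int]]:
    """(gamma, n_clusters) for every strength on the grid."""
    gamma_grid = np.asarray(gamma_grid, dtype=np.float64)
    if (gamma_grid < 0).any():
        raise ValueError("gamma grid must be >= 0")
    out = []
    for i, g in enumerate(gamma_grid):
        sm = similarity_matrix(tn, ps, float(g), transient, window, seed=seed + i)
        out.append((float(g), count_clusters(sm, threshold).n_clusters))
    return out


@dataclass
class ProjectionResult:
    """PCA basis fitted on pooled states, with per-trajectory projections."""

    components: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    projections: list[np.ndarray]
    pattern_projections: np.ndarray | None = None


def pc_projection(
    trajs: Sequence[Trajectory],
    n_components: int = 2,
    patterns: np.ndarray | None = None,
) -> ProjectionResult:
    """Principal axes of the pooled recorded states of several runs.

    Components are ordered by descending explained variance, with sign fixed
    so each component's largest-magnitude loading is positive.  Stored
    patterns may be projected onto the same axes for reference.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    pooled = np.vstack([t.states for t in trajs])
    if n_components > pooled.shape[1]:
        raise ValueError("n_components exceeds state dimension")
    if pooled.shape[0] < n_components:
        raise ValueError("fewer pooled samples than components")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(pooled)
    comps = pca.components_.copy()
    for c in comps:
        if c[np.argmax(np.abs(c))] < 0:
            c *= -1.0
    project = lambda X: (X - pca.mean_) @ comps.T
    return ProjectionResult(
        components=comps,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        mean=pca.mean_.copy(),
        projections=[project(t.states) for t in trajs],
        pattern_projections=None if patterns is None else project(np.asarray(patterns, float)),
    )
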