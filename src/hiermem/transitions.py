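"""Metastable-state transition statistics of spontaneous activity.

Spontaneous (gamma = 0) activity of a trained network wanders chaotically
and intermittently approaches the stored targets.  An "approach" is a
contiguous episode in which the overlap with at least one target exceeds a
threshold (default 0.5); within an episode the approached target is the one
with the highest overlap, time-stamped at that maximal overlap.  Consecutive
episodes on the same target are merged into one visit, so self-transitions
are excluded by construction.  From the visit sequence {(t_i, alpha_i)} the
pattern-level transition probabilities P_mu_nu (from nu to mu, columns
normalised over visited sources) and mean transition times T_mu_nu are
estimated, together with their category-level aggregates P'_ab and T'_ab.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Trajectory

__all__ = [
    "ApproachSequence",
    "TransitionStats",
    "CategoryBias",
    "detect_approaches",
    "approaches_from_overlaps",
    "transition_stats",
    "category_bias",
]


@dataclass
class ApproachSequence:
    """Ordered visits (t_i, alpha_i) of the state to targets."""

    times: np.ndarray
    targets: np.ndarray
    threshold: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if self.times.shape != self.targets.shape:
            raise ValueError("times and targets must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("approach times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


def approaches_from_overlaps(
    times: np.ndarray,
    overlaps: np.ndarray,
    threshold: float = 0.5,
    timestamp: str = "peak",
) -> ApproachSequence:
    """Extract the visit sequence from precomputed overlap traces.

    Parameters
    ----------
    times : (T,) array
        Recording times.
    overlaps : (T, K*M) array
        Overlap with every target at each time.
    threshold : float
        A time point belongs to an episode if any overlap exceeds this.
    timestamp : str
        "peak" stamps each visit at its maximal overlap; "entry" at the
        first suprathreshold sample of the (merged) visit.
    """
    times = np.asarray(times, dtype=np.float64)
    overlaps = np.asarray(overlaps, dtype=np.float64)
    if overlaps.ndim != 2 or overlaps.shape[0] != times.shape[0]:
        raise ValueError("overlaps must have shape (len(times), n_targets)")
    if timestamp not in ("peak", "entry"):
        raise ValueError("timestamp must be 'peak' or 'entry'")
    if len(times) == 0:
        raise ValueError("empty trajectory")

    above = overlaps.max(axis=1) > threshold
    # episode boundaries: runs of consecutive suprathreshold samples
    padded = np.r_[False, above, False]
    starts = np.flatnonzero(padded[1:-1] & ~padded[:-2])
    ends = np.flatnonzero(padded[1:-1] & ~padded[2:]) + 1  # exclusive

    visits: list[tuple[float, int, float, float]] = []  # (t, target, peak, entry_t)
    for s, e in zip(starts, ends):
        sub = overlaps[s:e]
        flat = int(np.argmax(sub))
        ti, tg = divmod(flat, sub.shape[1])
        peak = sub[ti, tg]
        t = times[s + ti] if timestamp == "peak" else times[s]
        if visits and visits[-1][1] == tg:
            # same target again without visiting another: one continued visit
            if peak > visits[-1][2]:
                prev = visits[-1]
                visits[-1] = (t if timestamp == "peak" else prev[0], tg, peak, prev[3])
        else:
            visits.append((t, tg, peak, times[s]))

    if not visits:
        return ApproachSequence(np.empty(0), np.empty(0, dtype=np.int64), threshold)
    t_out = [v[0] if timestamp == "peak" else v[3] for v in visits]
    return ApproachSequence(
        np.asarray(t_out), np.asarray([v[1] for v in visits]), threshold
    )


def detect_approaches(
    traj: Trajectory,
    targets: np.ndarray,
    threshold: float = 0.5,
    timestamp: str = "peak",
) -> ApproachSequence:
    """Visit sequence of a trajectory to a set of targets."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    targets = np.asarray(targets, dtype=np.float64)
    overlaps = traj.states @ targets.T / traj.n
    seq = approaches_from_overlaps(traj.times, overlaps, threshold, timestamp)
    seq.gamma = traj.gamma
    return seq


@dataclass
class TransitionStats:
    """Empirical transition matrices at pattern and category level.

    ``P[mu, nu]`` is the probability that a visit to target nu is followed by
    one to mu (columns over visited sources sum to 1, diagonal 0);
    ``T[mu, nu]`` the mean elapsed time of those transitions.  ``P_cat`` /
    ``T_cat`` aggregate over categories a = mu // M; their diagonals collect
    within-category moves between distinct targets.  Cells with no observed
    transition are NaN.
    """

    P: np.ndarray
    T: np.ndarray
    P_cat: np.ndarray
    T_cat: np.ndarray
    counts: np.ndarray
    n_transitions: int


def transition_stats(seq: ApproachSequence, km: int, m: int) -> TransitionStats:
    """Estimate P, T and their category aggregates from a visit sequence."""
    if km % m != 0:
        raise ValueError("km must be a multiple of m")
    k = km // m
    counts = np.zeros((km, km))
    tsum = np.zeros((km, km))
    if len(seq) < 2:
        warnings.warn("fewer than 2 visits; transition statistics are empty")
    else:
        src = seq.targets[:-1]
        dst = seq.targets[1:]
        gaps = np.diff(seq.times)
        np.add.at(counts, (dst, src), 1.0)
        np.add.at(tsum, (dst, src), gaps)

    def _normalise(c: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = c.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(col > 0, c / col, np.nan)
            t = np.where(c > 0, s / c, np.nan)
        return p, t

    P, T = _normalise(counts, tsum)
    np.fill_diagonal(P, 0.0)

    cat_counts = counts.reshape(k, m, k, m).sum(axis=(1, 3))
    cat_tsum = tsum.reshape(k, m, k, m).sum(axis=(1, 3))
    P_cat, T_cat = _normalise(cat_counts, cat_tsum)

    return TransitionStats(
        P=P,
        T=T,
        P_cat=P_cat,
        T_cat=T_cat,
        counts=counts,
        n_transitions=max(len(seq) - 1, 0),
    )


@dataclass
class CategoryBias:
    """Within- vs cross-category means of P' and T' (defined cells only)."""

    within_p: float
    cross_p: float
    within_t: float
    cross_t: float


def category_bias(stats: TransitionStats) -> CategoryBias:
    """Average the category matrices on and off the diagonal."""
    k = stats.P_cat.shape[0]
    diag = np.eye(k, dtype=bool)

    def _mean(mat: np.ndarray, mask: np.ndarray) -> float:
        vals = mat[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")

    return CategoryBias(
        within_p=_mean(stats.P_cat, diag),
        cross_p=_mean(stats.P_cat, ~diag),
        within_t=_mean(stats.T_cat, diag),
        cross_t=_mean(stats.T_cat, ~diag),
    )
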