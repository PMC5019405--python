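"""Overlaps with stored patterns, overlap profiles and bifurcation sweeps.

The overlap m^mu = sum_i x_i xi^mu_i / N measures how close the network state
is to stored pattern xi^mu (1 = exact match).  The overlap profile -- the
vector of temporal-mean overlaps with all K*M targets -- is the main readout:
flat for spontaneous activity, peaked on one category at intermediate input
strength, and peaked on a single target once the input is strong enough to
stabilise a recall fixed point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .dynamics import SimulationConfig, Trajectory, random_initial_state, simulate

if TYPE_CHECKING:  # pragma: no cover
    from .learning import TrainedNetwork
    from .patterns import PatternSet

__all__ = [
    "OverlapProfile",
    "BifurcationDiagram",
    "overlap",
    "overlap_trace",
    "overlap_profile",
    "localization_factor",
    "bifurcation_sweep",
]


def overlap(x: np.ndarray, pattern: np.ndarray) -> float:
    """Overlap sum_i x_i p_i / N between a state and a binary pattern."""
    x = np.asarray(x, dtype=np.float64)
    p = np.asarray(pattern, dtype=np.float64)
    if x.shape != p.shape or x.ndim != 1:
        raise ValueError("state and pattern must be 1-D arrays of equal length")
    return float(x @ p / x.size)


def overlap_trace(traj: Trajectory, pattern: np.ndarray) -> np.ndarray:
    """Overlap with ``pattern`` at every recorded time, shape (T,)."""
    p = np.asarray(pattern, dtype=np.float64)
    if p.shape != (traj.n,):
        raise ValueError(f"pattern must have shape ({traj.n},), got {p.shape}")
    return traj.states @ p / traj.n


@dataclass
class OverlapProfile:
    """Temporal mean and SD of the overlap with every target.

    The SD is the amplitude of temporal fluctuation around the mean over the
    analysis window, not a statistical error.
    """

    mu_index: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    transient: float
    window: float


def overlap_profile(
    traj: Trajectory,
    targets: np.ndarray,
    transient: float = 100.0,
    window: float = 400.0,
) -> OverlapProfile:
    """Profile of temporal-mean overlaps over ``window`` after ``transient``."""
    targets = np.asarray(targets, dtype=np.float64)
    if targets.ndim != 2 or targets.shape[1] != traj.n:
        raise ValueError("targets must have shape (K*M, N)")
    states = traj.window(transient, window)
    traces = states @ targets.T / traj.n  # (T, KM)
    return OverlapProfile(
        mu_index=np.arange(targets.shape[0]),
        mean=traces.mean(axis=0),
        sd=traces.std(axis=0),
        transient=transient,
        window=window,
    )


def localization_factor(profile: OverlapProfile) -> float:
    """Concentration index sigma of an overlap profile.

    Defined as the participation ratio of the rectified, normalised profile:
    with p_mu = max(mean_mu, 0) / sum_nu max(mean_nu, 0),

        sigma = sum_mu p_mu^2  in  [1/(K M), 1].

    sigma = 1 when a single target carries all positive overlap, 1/(K*M)
    when the profile is uniform.  Negative mean overlaps are rectified to
    zero because localization concerns proximity to targets, not
    anti-alignment.  Returns NaN (with a warning) if no mean is positive.
    """
    p = np.clip(profile.mean, 0.0, None)
    total = p.sum()
    if total <= 0.0:
        warnings.warn("all mean overlaps non-positive; localization undefined")
        return float("nan")
    p = p / total
    return float((p**2).sum())


@dataclass
class BifurcationDiagram:
    """Sampled overlaps with one target across an input-strength grid.

    ``samples[i]`` holds the overlap with target ``mu`` sampled every
    ``sample_interval`` unit time over ``sample_span`` after the transient,
    at strength ``gammas[i]``; scattered samples signal wandering dynamics,
    a collapsed column a fixed point.
    """

    gammas: np.ndarray
    samples: np.ndarray
    mu: int
    transient: float
    sample_interval: float = 5.0
    sample_span: float = 250.0
    lyapunov: np.ndarray | None = None


def bifurcation_sweep(
    tn: "TrainedNetwork",
    ps: "PatternSet",
    mu: int,
    gammas: np.ndarray,
    transient: float = 100.0,
    sample_interval: float = 5.0,
    sample_span: float = 250.0,
    seed: int = 0,
    with_lyapunov: bool = False,
    lyapunov_kwargs: dict | None = None,
) -> BifurcationDiagram:
    """Overlap samples with target ``mu`` under input ``mu`` for each gamma.

    Samples are taken at t = transient + k * sample_interval for
    k = 1 .. floor(sample_span / sample_interval) (50 samples with the
    defaults).  Each strength starts from a fresh random initial state.
    """
    gammas = np.asarray(gammas, dtype=np.float64)
    if (gammas < 0).any():
        raise ValueError("gammas must be >= 0")
    n_samp = int(np.floor(sample_span / sample_interval))
    dt = tn.config.dt
    cfg = SimulationConfig(duration=transient + sample_span, dt=dt, transient=transient)
    seeds = np.random.SeedSequence(seed).spawn(len(gammas))
    sample_t = transient + sample_interval * np.arange(1, n_samp + 1)

    samples = np.empty((len(gammas), n_samp))
    lams = np.empty(len(gammas)) if with_lyapunov else None
    for i, g in enumerate(gammas):
        x0 = random_initial_state(ps.spec.n, np.random.default_rng(seeds[i]))
        traj = simulate(tn.network, ps.inputs[mu], float(g), x0, cfg, mu=mu)
        trace = overlap_trace(traj, ps.targets[mu])
        idx = np.searchsorted(traj.times, sample_t - 1e-9)
        samples[i] = trace[np.minimum(idx, len(trace) - 1)]
        if with_lyapunov:
            from .chaos import largest_lyapunov

            kw = dict(duration=1000.0, transient=100.0, seed=seed)
            kw.update(lyapunov_kwargs or {})
            lams[i] = largest_lyapunov(
                tn.network, ps.inputs[mu], float(g), **kw
            ).lam
    return BifurcationDiagram(
        gammas=gammas,
        samples=samples,
        mu=mu,
        transient=transient,
        sample_interval=sample_interval,
        sample_span=sample_span,
        lyapunov=lams,
    )
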