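"""Concurrent neural and synaptic dynamics: training and recall evaluation.

While an input pattern eta^mu is applied at strength Gamma, the synapses
follow a perceptron-like supervised rule driven by the mismatch between the
activity and the associated target xi^mu:

    dJ_ij/dt = alpha * (xi_i - x_i) * x_j      (diagonal pinned at 0)

Neural and synaptic dynamics are Euler-stepped together with the same dt;
within one step the J update uses the pre-step state, so neither update leaks
into the other.  Associations are presented for ``presentation_time`` each,
in a fresh random permutation of all K*M associations per epoch (optionally
i.i.d. with replacement), and the neural state carries over from one
presentation to the next.  The initial J has entries drawn uniformly from
{-1, +1} with zero diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import Network, SimulationConfig, random_initial_state, simulate
from .overlap import overlap_trace
from .patterns import PatternSet, PatternSpec

__all__ = [
    "LearningConfig",
    "TrainedNetwork",
    "RecallReport",
    "TrainingError",
    "learning_derivative",
    "train",
    "evaluate_recall",
]


class TrainingError(RuntimeError):
    """Raised when J becomes non-finite during training."""


@dataclass(frozen=True)
class LearningConfig:
    """Hyperparameters of the supervised learning process.

    Attributes
    ----------
    alpha : float
        Synaptic learning rate per unit time (relative to the neural
        relaxation rate).
    gamma_train : float
        Input strength Gamma applied during learning.
    epochs : int
        Number of passes over all K*M associations.
    presentation_time : float
        Duration (unit time) each association is presented.
    dt : float
        Shared Euler step for x and J.
    seed : int
        Seeds initial J, initial x and presentation order.
    beta : float
        Neural gain.
    order : str
        "permute" (fresh permutation per epoch) or "replacement"
        (i.i.d. draws, epochs * K * M presentations in total).
    reset_state : bool
        If True, redraw x at the start of every presentation (ablation;
        default carries the state over).
    j_scale : float
        Multiplier on the initial +/-1 synapses.
    stop_tol : float or None
        Optional early stop within a presentation once mean |xi - x| falls
        below this value.
    """

    alpha: float = 0.01
    gamma_train: float = 16.0
    epochs: int = 100
    presentation_time: float = 10.0
    dt: float = 0.01
    seed: int = 0
    beta: float = 4.0
    order: str = "permute"
    reset_state: bool = False
    j_scale: float = 1.0
    stop_tol: float | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.gamma_train <= 0:
            raise ValueError("gamma_train must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.presentation_time <= 0:
            raise ValueError("presentation_time must be > 0")
        if not 0.0 < self.dt <= 1.0:
            raise ValueError("dt must satisfy 0 < dt <= 1")
        if self.order not in ("permute", "replacement"):
            raise ValueError("order must be 'permute' or 'replacement'")


@dataclass
class TrainedNetwork:
    """Final network plus provenance and per-presentation diagnostics.

    ``history`` holds the mean absolute target error |xi - x| at the end of
    each presentation, in presentation order.
    """

    network: Network
    pattern_spec: PatternSpec
    config: LearningConfig
    history: np.ndarray | None = None
    presented: np.ndarray | None = None


@dataclass
class RecallReport:
    """Per-association mean target overlap under the associated input."""

    overlaps: np.ndarray
    gamma: float
    threshold: float = 0.9

    @property
    def success_fraction(self) -> float:
        """Fraction of associations whose mean overlap exceeds the threshold."""
        return float((self.overlaps > self.threshold).mean())


def learning_derivative(x: np.ndarray, xi: np.ndarray, alpha: float) -> np.ndarray:
    """dJ/dt = alpha (xi - x) x^T with zero diagonal."""
    x = np.asarray(x, dtype=np.float64)
    xi = np.asarray(xi, dtype=np.float64)
    if x.shape != xi.shape or x.ndim != 1:
        raise ValueError("x and xi must be 1-D arrays of equal length")
    dj = alpha * np.outer(xi - x, x)
    np.fill_diagonal(dj, 0.0)
    return dj


def train(ps: PatternSet, lc: LearningConfig) -> TrainedNetwork:
    """Train a network on all associations of ``ps``.

    Deterministic given (ps, lc).  Raises :class:`TrainingError` with the
    offending presentation index if J diverges.
    """
    rng = np.random.default_rng(lc.seed)
    n, n_assoc = ps.spec.n, ps.n_assoc
    J = (rng.integers(0, 2, size=(n, n)) * 2.0 - 1.0) * lc.j_scale
    np.fill_diagonal(J, 0.0)
    x = rng.uniform(-1.0, 1.0, size=n)

    inputs = ps.inputs.astype(np.float64)
    targets = ps.targets.astype(np.float64)
    dt, alpha, beta, gamma = lc.dt, lc.alpha, lc.beta, lc.gamma_train
    steps = int(round(lc.presentation_time / dt))
    a_dt = alpha * dt

    if lc.order == "permute":
        schedule = np.concatenate([rng.permutation(n_assoc) for _ in range(lc.epochs)])
    else:
        schedule = rng.integers(0, n_assoc, size=lc.epochs * n_assoc)

    history = np.empty(len(schedule))
    for p, mu in enumerate(schedule):
        drive = gamma * inputs[mu]
        xi = targets[mu]
        if lc.reset_state:
            x = rng.uniform(-1.0, 1.0, size=n)
        for _ in range(steps):
            # both updates read the pre-step (x, J)
            x_new = (1.0 - dt) * x + dt * np.tanh(beta * (J @ x + drive))
            err = xi - x
            J += a_dt * np.outer(err, x)
            np.fill_diagonal(J, 0.0)
            x = x_new
            if lc.stop_tol is not None and np.abs(err).mean() < lc.stop_tol:
                break
        if not np.isfinite(J).all():
            raise TrainingError(f"non-finite J after presentation {p} (mu={mu})")
        history[p] = np.abs(xi - x).mean()

    return TrainedNetwork(
        network=Network(J=J, beta=beta),
        pattern_spec=ps.spec,
        config=lc,
        history=history,
        presented=schedule,
    )


def evaluate_recall(
    tn: TrainedNetwork,
    ps: PatternSet,
    gamma: float,
    transient: float = 100.0,
    window: float = 400.0,
    threshold: float = 0.9,
    seed: int = 0,
    dt: float | None = None,
) -> RecallReport:
    """Mean target overlap under each association's own input.

    For every association mu the network is run from a fresh random initial
    state under input mu at strength ``gamma``; the overlap with target mu is
    averaged over ``window`` unit time after a ``transient``.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    cfg = SimulationConfig(
        duration=transient + window, dt=dt or tn.config.dt, transient=transient
    )
    seeds = np.random.SeedSequence(seed).spawn(ps.n_assoc)
    means = np.empty(ps.n_assoc)
    for mu in range(ps.n_assoc):
        x0 = random_initial_state(ps.spec.n, np.random.default_rng(seeds[mu]))
        traj = simulate(tn.network, ps.inputs[mu], gamma, x0, cfg, mu=mu)
        trace = overlap_trace(traj, ps.targets[mu])
        mask = (traj.times > transient) & (traj.times <= transient + window)
        means[mu] = trace[mask].mean()
    return RecallReport(overlaps=means, gamma=gamma, threshold=threshold)
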