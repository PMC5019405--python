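"""Rate-model dynamics of the recurrent network.

Each of N neurons carries a continuous activity x_i in [-1, 1] evolving as

    dx_i/dt = tanh( beta * ( sum_{j != i} J_ij x_j + gamma * eta_i ) ) - x_i

where J is the (zero-diagonal) synaptic matrix, eta a binary input pattern
and gamma its strength.  Time is measured in units of the relaxation time of
a neuron.  Integration uses forward Euler with dt <= 1, for which each update
is a convex combination of the previous state and a tanh value, so recorded
states stay in [-1, 1] for any input.  Spontaneous activity is the gamma = 0
case (no input pattern).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Network",
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "derivative",
    "simulate",
    "random_initial_state",
]


class IntegrationError(RuntimeError):
    """Raised when the state becomes non-finite during integration."""


@dataclass
class Network:
    """A recurrent network: synaptic matrix J (j -> i) and gain beta.

    The diagonal of J is forced to zero on construction (no self-connections);
    passing a matrix with a nonzero diagonal is allowed and has no effect on
    the dynamics.
    """

    J: np.ndarray
    beta: float = 4.0

    def __post_init__(self) -> None:
        J = np.array(self.J, dtype=np.float64)
        if J.ndim != 2 or J.shape[0] != J.shape[1]:
            raise ValueError(f"J must be square, got shape {J.shape}")
        if not np.isfinite(J).all():
            raise ValueError("J must be finite")
        np.fill_diagonal(J, 0.0)
        self.J = J

    @property
    def n(self) -> int:
        return self.J.shape[0]


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings (times in unit time)."""

    duration: float
    dt: float = 0.01
    transient: float = 100.0
    record_stride: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.dt <= 1.0:
            raise ValueError("dt must satisfy 0 < dt <= 1")
        if not self.duration > self.transient >= 0.0:
            raise ValueError("need duration > transient >= 0")
        if self.record_stride < self.dt:
            raise ValueError("record_stride must be >= dt")


@dataclass
class Trajectory:
    """Recorded states of one simulation run.

    ``states`` has shape (T, N); ``times`` is strictly increasing and starts
    at 0.  ``mu`` is the index of the applied input, or None for spontaneous
    activity; ``gamma`` the applied input strength.
    """

    times: np.ndarray
    states: np.ndarray
    gamma: float
    mu: int | None = None
    dt: float = 0.01
    record_stride: float = 0.1

    @property
    def n(self) -> int:
        return self.states.shape[1]

    def __len__(self) -> int:
        return self.states.shape[0]

    def window(self, start: float, length: float) -> np.ndarray:
        """States recorded in the half-open time interval (start, start+length]."""
        mask = (self.times > start) & (self.times <= start + length)
        if not mask.any():
            raise ValueError(
                f"trajectory (t <= {self.times[-1]:g}) has no samples in "
                f"({start:g}, {start + length:g}]"
            )
        return self.states[mask]


def _drive(net: Network, input_pattern: np.ndarray | None, gamma: float) -> np.ndarray:
    if input_pattern is None:
        return np.zeros(net.n)
    eta = np.asarray(input_pattern, dtype=np.float64)
    if eta.shape != (net.n,):
        raise ValueError(f"input pattern must have shape ({net.n},), got {eta.shape}")
    return gamma * eta


def derivative(
    x: np.ndarray,
    net: Network,
    input_pattern: np.ndarray | None = None,
    gamma: float = 0.0,
) -> np.ndarray:
    """Right-hand side tanh(beta(Jx + gamma*eta)) - x of the rate equation."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (net.n,):
        raise ValueError(f"state must have shape ({net.n},), got {x.shape}")
    return np.tanh(net.beta * (net.J @ x + _drive(net, input_pattern, gamma))) - x


def random_initial_state(n: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniform i.i.d. initial state in [-1, 1]^n (deterministic given seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.uniform(-1.0, 1.0, size=n)


def simulate(
    net: Network,
    input_pattern: np.ndarray | None,
    gamma: float,
    x0: np.ndarray,
    cfg: SimulationConfig,
    mu: int | None = None,
) -> Trajectory:
    """Forward-Euler integration of the rate equation.

    Records the state at t = 0 and every ``record_stride`` thereafter.
    Raises :class:`IntegrationError` (with the offending time) if the state
    becomes non-finite.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    x = np.array(x0, dtype=np.float64)
    if x.shape != (net.n,):
        raise ValueError(f"x0 must have shape ({net.n},), got {x.shape}")
    if np.abs(x).max() > 1.0:
        raise ValueError("x0 must lie in [-1, 1]^N")

    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    stride = max(1, int(round(cfg.record_stride / dt)))
    drive = _drive(net, input_pattern, gamma)
    beta, J = net.beta, net.J

    n_rec = n_steps // stride + 1
    states = np.empty((n_rec, net.n))
    times = np.empty(n_rec)
    states[0], times[0] = x, 0.0
    k = 1
    for step in range(1, n_steps + 1):
        x = (1.0 - dt) * x + dt * np.tanh(beta * (J @ x + drive))
        if step % stride == 0:
            if not np.isfinite(x).all():
                raise IntegrationError(f"non-finite state at t = {step * dt:g}")
            states[k], times[k] = x, step * dt
            k += 1
    return Trajectory(
        times=times[:k],
        states=states[:k],
        gamma=gamma if input_pattern is not None else 0.0,
        mu=mu,
        dt=dt,
        record_stride=stride * dt,
    )
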