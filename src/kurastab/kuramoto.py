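"""Noise-free delayed Kuramoto dynamics on structural networks.

Each node n is a phase oscillator whose update under forward-Euler integration
(one step = ``dt`` seconds) is

    theta_n(t+1) = theta_n(t) + omega_n
                   + sum_p K_np * sin(theta_p(t - tau_np) - theta_n(t))

with intrinsic angular velocity omega_n = 2*pi*f_n*dt (f_n in Hz, drawn from a
configured band), coupling K_np proportional to the structural weight C_np, and
integer conduction delays tau_np obtained by dividing tract lengths (mm) by 20
and rounding.  With the default dt = 1 ms that delay rule corresponds to a
20 m/s conduction velocity and 2,000 steps span 2 s of simulated time.  The
model is deliberately noise-free: multistability is probed by resampling
initial conditions, not by stochastic exploration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_core import StructuralNetwork

__all__ = [
    "DynamicalSystem",
    "PhaseTrajectory",
    "SimulationError",
    "sample_frequencies",
    "build_system",
    "random_initial_phases",
    "simulate",
]

TWO_PI = 2.0 * np.pi

#: mm of tract length per integration step of conduction delay (20 m/s at 1 ms/step)
LENGTH_PER_DELAY_STEP_MM = 20.0


class SimulationError(RuntimeError):
    """Integration produced non-finite phases."""


def sample_frequencies(
    n: int, band_hz: tuple[float, float] = (25.0, 75.0), seed: int | None = None
) -> np.ndarray:
    """Draw ``n`` intrinsic frequencies uniformly from ``band_hz`` (Hz).

    The default band is the gamma range, 25-75 Hz.
    """
    low, high = band_hz
    if not (0 < low <= high):
        raise ValueError(f"invalid frequency band {band_hz}")
    return np.random.default_rng(seed).uniform(low, high, size=n)


@dataclass(frozen=True)
class DynamicalSystem:
    """A structural network bound to one intrinsic-frequency vector.

    ``omega`` is in rad/step, ``coupling`` is the fully assembled K matrix
    (zero where there is no edge) and ``delay_steps`` the integer delay matrix.
    One frequency vector on one network is the unit whose multistability is
    assessed.
    """

    network: StructuralNetwork
    omega: np.ndarray
    coupling: np.ndarray
    delay_steps: np.ndarray
    dt: float
    k_global: float
    freqs_hz: np.ndarray = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return self.network.n_nodes

    @property
    def max_delay(self) -> int:
        return int(self.delay_steps.max()) if self.delay_steps.size else 0


def build_system(
    net: StructuralNetwork,
    freqs_hz: np.ndarray,
    k_global: float = 1000.0,
    dt: float = 0.001,
    normalize_by_n: bool = True,
) -> DynamicalSystem:
    """Assemble a :class:`DynamicalSystem` from a network and frequencies.

    Parameters
    ----------
    freqs_hz
        Intrinsic frequencies in Hz, one per node.
    k_global
        Global coupling scale; the canonical mean-field normalisation
        K_np = k_global * C_np / N applies unless ``normalize_by_n`` is False,
        in which case K_np = k_global * C_np.
    dt
        Step duration in seconds (default 1 ms).
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if freqs_hz.shape != (net.n_nodes,):
        raise ValueError(f"expected {net.n_nodes} frequencies, got {freqs_hz.shape}")
    if dt <= 0:
        raise ValueError("dt must be positive")
    omega = TWO_PI * freqs_hz * dt
    coupling = k_global * net.weights
    if normalize_by_n:
        coupling = coupling / net.n_nodes
    delay = np.rint(net.lengths / LENGTH_PER_DELAY_STEP_MM).astype(int)
    delay[net.weights == 0] = 0
    np.fill_diagonal(delay, 0)
    return DynamicalSystem(net, omega, coupling, delay, dt, k_global, freqs_hz)


@dataclass(frozen=True)
class PhaseTrajectory:
    """Unwrapped per-node phases from one simulation run.

    ``phases`` is T x N (row 0 is the initial condition); the first ``burn_in``
    rows are flagged as pre-stabilisation transient and discarded by all
    synchrony computations.
    """

    phases: np.ndarray
    dt: float
    burn_in: int = 100

    @property
    def n_steps(self) -> int:
        return self.phases.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[1]

    def signals(self) -> np.ndarray:
        """Render the oscillatory traces sin(theta) (T x N)."""
        return np.sin(self.phases)


def random_initial_phases(n: int, seed: int | None = None) -> np.ndarray:
    """Uniform initial phases on [0, 2*pi), one per node."""
    return np.random.default_rng(seed).uniform(0.0, TWO_PI, size=n)


def simulate(
    system: DynamicalSystem,
    n_steps: int = 2000,
    init_phases: np.ndarray | int | None = None,
    burn_in: int = 100,
    random_history: bool = False,
) -> PhaseTrajectory:
    """Integrate the delayed Kuramoto map for ``n_steps`` Euler steps.

    ``init_phases`` may be an explicit N-vector or a seed for uniform random
    initial phases.  Phase history for t < 0 is held constant at each node's
    initial phase (or, with ``random_history``, drawn uniformly per delayed
    slot from the same seed stream).  Identical inputs give an identical
    trajectory.
    """
    n = system.n_nodes
    d = system.max_delay
    if n_steps <= d + burn_in:
        raise ValueError(
            f"n_steps={n_steps} must exceed max delay ({d}) + burn-in ({burn_in})"
        )
    if init_phases is None or np.isscalar(init_phases):
        seed = None if init_phases is None else int(init_phases)
        rng = np.random.default_rng(seed)
        theta0 = rng.uniform(0.0, TWO_PI, size=n)
    else:
        theta0 = np.asarray(init_phases, dtype=float)
        if theta0.shape != (n,):
            raise ValueError(f"init_phases must have shape ({n},)")
        rng = None

    buf = np.empty((d + n_steps, n))
    if random_history and d > 0:
        if rng is None:
            rng = np.random.default_rng()
        buf[:d] = rng.uniform(0.0, TWO_PI, size=(d, n))
    else:
        buf[:d] = theta0
    buf[d] = theta0

    k = system.coupling
    omega = system.omega
    has_delay = d > 0
    if has_delay:
        # row_idx[n_, p] selects theta_p(t - tau_np) from the rolling buffer
        col_idx = np.broadcast_to(np.arange(n), (n, n))
        delay = system.delay_steps
    for t in range(n_steps - 1):
        cur = buf[d + t]
        if has_delay:
            delayed = buf[d + t - delay, col_idx]
        else:
            delayed = np.broadcast_to(cur, (n, n))
        incr = omega + np.einsum("np,np->n", k, np.sin(delayed - cur[:, None]))
        buf[d + t + 1] = cur + incr
    phases = buf[d:]
    if not np.all(np.isfinite(phases)):
        bad = int(np.argwhere(~np.isfinite(phases))[0, 0])
        raise SimulationError(f"non-finite phase at step {bad}")
    return PhaseTrajectory(phases.copy(), system.dt, burn_in)
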